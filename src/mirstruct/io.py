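"""File I/O for the pipeline's standard formats.

FASTA reading accepts plain or gzipped multi-record files (Biopython).
Two TSV dialects double as the adapter seam for externally computed
folding results: per-feature window MFEs (feature_id, window_start_0based,
mfe) and sparse pair probabilities (feature_id, i, j, prob; 1-based,
i < j), so window scans or base-pair matrices produced by standard
folding tools can be fed into the downstream callers unchanged.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .ensemble import EnsembleResult
from .fold import WindowProfile
from .methylation import MethylationData
from .seqs import InputError, NucleotideSequence
from .smrna import SpeciesTable


def read_fasta(path) -> dict[str, NucleotideSequence]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: NucleotideSequence(rec.id, str(rec.seq))
                for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            residues = seq.residues if isinstance(seq, NucleotideSequence) \
                else str(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i:i + width] + "\n")


def write_window_mfe_tsv(profiles, path) -> None:
    rows = []
    for prof in profiles:
        for start, mfe in zip(prof.starts, prof.window_mfes):
            rows.append((prof.feature_id, int(start), float(mfe)))
    pd.DataFrame(rows, columns=["feature_id", "window_start_0based", "mfe"]) \
        .to_csv(path, sep="\t", index=False)


def read_window_mfe_tsv(path, window_size: int = 110,
                        lengths: dict[str, int] | None = None
                        ) -> dict[str, WindowProfile]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, WindowProfile] = {}
    for fid, grp in df.groupby("feature_id", sort=False):
        starts = grp["window_start_0based"].to_numpy(dtype=np.int64)
        mfes = grp["mfe"].to_numpy(dtype=float)
        step = int(starts[1] - starts[0]) if len(starts) > 1 else 1
        length = (lengths or {}).get(
            str(fid), int(starts.max()) + window_size)
        out[str(fid)] = WindowProfile(
            feature_id=str(fid), window_size=window_size, step=step,
            starts=starts, window_mfes=mfes,
            short_feature=length < window_size, length=length)
    return out


def write_pair_prob_tsv(ensembles, path, min_prob: float = 1e-4) -> None:
    """Sparse upper-triangle pair probabilities, 1-based, i < j."""
    rows = []
    for ens in ensembles:
        iu, ju = np.triu_indices(ens.length, k=1)
        keep = ens.pair_prob[iu, ju] >= min_prob
        for i, j in zip(iu[keep], ju[keep]):
            rows.append((ens.feature_id, int(i) + 1, int(j) + 1,
                         float(ens.pair_prob[i, j])))
    pd.DataFrame(rows, columns=["feature_id", "i", "j", "prob"]) \
        .to_csv(path, sep="\t", index=False)


def read_pair_prob_tsv(path, lengths: dict[str, int],
                       log_z: dict[str, float] | None = None
                       ) -> dict[str, EnsembleResult]:
    """Adapter input: externally computed base-pair probability matrices.

    ``lengths`` maps feature_id to sequence length; ``log_z`` optionally
    supplies ln(Z) so Q can be carried through (NaN otherwise).
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, EnsembleResult] = {}
    for fid, grp in df.groupby("feature_id", sort=False):
        fid = str(fid)
        if fid not in lengths:
            raise InputError(f"no length given for feature {fid}")
        n = lengths[fid]
        pp = np.zeros((n, n))
        i = grp["i"].to_numpy(dtype=int) - 1
        j = grp["j"].to_numpy(dtype=int) - 1
        if (i >= j).any() or (j >= n).any() or (i < 0).any():
            raise InputError(f"bad pair indices for feature {fid}")
        pp[i, j] = grp["prob"].to_numpy(dtype=float)
        pp[j, i] = pp[i, j]
        lz = (log_z or {}).get(fid, float("nan"))
        res = EnsembleResult(fid, n, lz, pp)
        res._q = float("nan") if np.isnan(lz) else -0.6157 * lz
        out[fid] = res
    return out


def read_species_tsv(path, length_class: int,
                     library_id: str = "lib") -> SpeciesTable:
    """Collapsed smRNA table: two columns (sequence, count)."""
    df = pd.read_csv(path, sep="\t")
    seqs = df.iloc[:, 0].astype(str)
    counts = df.iloc[:, 1].astype(int)
    species = {}
    for s, c in zip(seqs, counts):
        s = s.upper().replace("T", "U")
        if len(s) == length_class:
            species[s] = species.get(s, 0) + int(c)
    return SpeciesTable(library_id, length_class, species)


def write_species_tsv(table: SpeciesTable, path) -> None:
    pd.DataFrame(sorted(table.species.items()),
                 columns=["sequence", "count"]) \
        .to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path) -> MethylationData:
    """CX-report-like dialect: chrom, 1-based pos, strand, context,
    meth_reads, total_reads; converted to 0-based internally."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "pos", "strand", "context", "meth",
                            "total"],
                     header=0, dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    return MethylationData(df)


def write_methylation_tsv(meth: MethylationData, path) -> None:
    df = meth.frame.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", index=False,
              columns=["chrom", "pos", "strand", "context", "meth", "total"])
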