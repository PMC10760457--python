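"""Genomic feature annotations and GFF3/BED interchange.

Features carry a category from a controlled vocabulary: ``gene``,
``transcript``, ``miRNA``, or a Wicker-style three-letter transposable-
element superfamily code (RLC Copia, RLG Ty3, RLX unknown LTR, RIL/RIT
LINEs, RST SINEs, DTA hAT, DTC CACTA, DTH Harbinger, DTM Mutator,
DTT Tc1-Mariner, DHH helitron).  Unknown codes pass through with a
warning rather than failing, since annotation sources vary.

Coordinates are 0-based half-open internally and in BED; GFF3 I/O
converts the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .seqs import InputError

TE_SUPERFAMILIES = ("RLC", "RLG", "RLX", "RIL", "RIT", "RST",
                    "DTA", "DTC", "DTH", "DTM", "DTT", "DHH")
CATEGORIES = ("gene", "transcript", "miRNA", "control") + TE_SUPERFAMILIES
AUTONOMY = ("autonomous", "nonautonomous", "unknown")


@dataclass(frozen=True)
class FeatureAnnotation:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    feature_id: str
    category: str
    autonomy: str = "unknown"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(
                f"feature {self.feature_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise InputError(f"feature {self.feature_id}: bad strand")
        if self.category not in CATEGORIES:
            warnings.warn(
                f"feature {self.feature_id}: unknown category "
                f"{self.category!r} passed through", stacklevel=2)
        if self.autonomy not in AUTONOMY:
            raise InputError(f"feature {self.feature_id}: bad autonomy")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_genomic(self, local_start: int, local_end: int) -> tuple[int, int]:
        """Translate feature-local sense-strand offsets to genomic
        coordinates, honouring strand."""
        if self.strand == "+":
            return self.start + local_start, self.start + local_end
        return self.end - local_end, self.end - local_start


def write_gff3(features, path, extra_attrs: dict | None = None) -> None:
    """Write features as GFF3 (1-based inclusive on disk)."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.feature_id}", f"category={f.category}",
                     f"autonomy={f.autonomy}"]
            for k, v in extra_attrs.get(f.feature_id, {}).items():
                attrs.append(f"{k}={v}")
            ftype = "gene" if f.category in ("gene", "transcript") else \
                ("miRNA" if f.category == "miRNA" else "transposable_element")
            fh.write("\t".join([
                f.chrom, "mirstruct", ftype, str(f.start + 1), str(f.end),
                ".", f.strand, ".", ";".join(attrs)]) + "\n")


def read_gff3(path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"chrom": str})
    feats = []
    for row in df.itertuples(index=False):
        attrs = dict(kv.split("=", 1) for kv in str(row.attributes).split(";")
                     if "=" in kv)
        feats.append(FeatureAnnotation(
            chrom=row.chrom, start=int(row.start) - 1, end=int(row.end),
            strand=row.strand if row.strand in "+-" else "+",
            feature_id=attrs.get("ID", f"{row.chrom}:{row.start}-{row.end}"),
            category=attrs.get("category", row.type),
            autonomy=attrs.get("autonomy", "unknown"),
        ))
    return feats


def write_bed(intervals, path, header_comment: str | None = None) -> None:
    """BED6 writer; ``intervals`` yields (chrom, start, end, name, score,
    strand)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df
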