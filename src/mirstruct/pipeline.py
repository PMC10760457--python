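"""End-to-end orchestration: fold -> call -> map -> skew -> methylation ->
expression, with file artifacts and a run report.

Every stage writes plain TSV/BED artifacts under the output directory and
records its numbers in the run report; every report number is
recomputable from the emitted files.  The whole pipeline is a pure
function of (inputs, config, seed): a rerun with the same configuration
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotations import write_bed, write_gff3, read_gff3
from .energy import EnergyModel
from .ensemble import partition_function
from .expression import (compare_structured_expression, cv_frame,
                         fit_cv_models, quartile_smrna_summary)
from .fold import window_scan
from .methylation import (MethylationData, draw_control_window,
                          feature_landscape, methylation_metaprofile,
                          overlap_enrichment)
from .seqs import InputError, shuffle_sequence
from .simulate import (SyntheticConfig, build_synthetic_genome,
                       simulate_expression_panel, simulate_methylome,
                       simulate_smrna_libraries)
from .smrna import (SpeciesTable, compute_skew, hits_to_frame,
                    map_species_exact, skew_frame, skew_sign_test)
from .structure import calibrate_mfe_threshold, summarize_structures

log = logging.getLogger("mirstruct")

STAGES = ("simulate", "fold", "call", "smrna", "skew", "methprofile",
          "landscape", "enrich", "expression")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    window_size: int = 110
    step: int = 1
    mfe_threshold: float = -40.0
    n_shuffles: int = 5
    alpha: float = 0.05
    p_min: float = 0.90
    min_span: int = 21
    max_mismatch: int = 4
    max_asym: int = 2
    flank: int = 2000
    meth_window: int = 100
    bins: int = 100
    seed: int = 0
    engine: str = "builtin"          # builtin | external-import
    calibrate_threshold: bool = True  # builtin model: threshold from shuffles
    calibrate_quantile: float = 0.005
    skew_regions: str = "lowmfe"      # lowmfe | hairpin
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0 < self.p_min < 1):
            raise ConfigError("p_min must lie in (0, 1)")
        if self.window_size < 5:
            raise ConfigError("window_size too small")
        if self.n_shuffles < 1:
            raise ConfigError("n_shuffles must be >= 1")
        if self.engine not in ("builtin", "external-import"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if self.skew_regions not in ("lowmfe", "hairpin"):
            raise ConfigError("skew_regions must be 'lowmfe' or 'hairpin'")
        if self.min_span < 2 * self.max_mismatch:
            log.warning("degenerate hairpin regime: min_span %d with "
                        "max_mismatch %d", self.min_span, self.max_mismatch)

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """YAML config with defaults; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _synthetic_config(cfg: PipelineConfig) -> SyntheticConfig:
    from .simulate import CategoryConfig

    raw = dict(cfg.synthetic)
    cats = raw.pop("categories", None)
    sc = SyntheticConfig(seed=cfg.seed, **raw)
    if cats:
        sc.categories = {name: CategoryConfig(**c) for name, c in cats.items()}
    return sc


@dataclass
class RunState:
    """In-memory hand-off between stages (files are the durable form)."""

    dataset: object = None
    profiles: dict = None
    shuffled: dict = None
    ensembles: dict = None
    summaries: dict = None
    regions: dict = None
    hairpins: dict = None
    threshold: float = None
    species_tables: dict = None
    hits: dict = None
    methylome: MethylationData = None
    tissue_expr: pd.DataFrame = None
    line_expr: pd.DataFrame = None
    skew_records: list = None


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stages=STAGES,
) -> dict:
    """Execute the requested stages in dependency order; returns the run
    report (also written to ``report.json``)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = RunState()
    report: dict = {"config": asdict(config),
                    "fingerprint": config.fingerprint(), "stages": {}}
    order = [s for s in STAGES if s in stages]
    for stage in order:
        t0 = time.time()
        log.info("stage %s: start (fingerprint %s)", stage,
                 config.fingerprint())
        _STAGE_FUNCS[stage](config, out, state, report)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


# --------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, out, state, report):
    sc = _synthetic_config(cfg)
    dataset = build_synthetic_genome(sc)
    state.dataset = dataset
    mio.write_fasta(dataset.genome, out / "genome.fasta")
    write_gff3(dataset.features, out / "features.gff3")
    dataset.truth.to_json(out / "truth.json")
    libs = simulate_smrna_libraries(dataset, sc)
    state.species_tables = {}
    for (lib, k), df in libs.items():
        df.to_csv(out / f"smrna_{lib}_{k}nt.tsv", sep="\t", index=False)
        state.species_tables[(lib, k)] = SpeciesTable(
            lib, k, dict(zip(df["sequence"], df["count"])))
    meth_df = simulate_methylome(dataset, sc)
    state.methylome = MethylationData(meth_df)
    mio.write_methylation_tsv(state.methylome, out / "methylation.tsv")
    # expression needs smRNA densities per gene
    dens = _gene_density_from_tables(dataset, state.species_tables)
    tissue, line = simulate_expression_panel(dataset, sc, dens)
    tissue.to_csv(out / "expression_tissues.tsv", sep="\t")
    line.to_csv(out / "expression_lines.tsv", sep="\t")
    state.tissue_expr, state.line_expr = tissue, line
    report["n_features"] = len(dataset.features)
    report["genome_bp"] = sum(len(s) for s in dataset.genome.values())


def _gene_density_from_tables(dataset, tables) -> dict[str, float]:
    """Crude per-gene species-per-kb from the simulated tables: counts of
    species whose sequence occurs in the gene (exact, either strand)."""
    from .seqs import reverse_complement

    dens: dict[str, float] = {}
    genes = [f for f in dataset.features if f.category == "gene"]
    if not genes:
        return dens
    per_gene = {g.feature_id: 0 for g in genes}
    for (lib, k), table in tables.items():
        lookup = set()
        for sp in table.species:
            lookup.add(sp)
            lookup.add(reverse_complement(sp))
        for g in genes:
            seq = dataset.genome[g.chrom][g.start:g.end]
            hits = 0
            for i in range(len(seq) - k + 1):
                if seq[i:i + k] in lookup:
                    hits += 1
            per_gene[g.feature_id] += hits
    for g in genes:
        dens[g.feature_id] = per_gene[g.feature_id] / g.length * 1000.0
    return dens


def _require_dataset(cfg, out, state):
    if state.dataset is None:
        fasta = out / "genome.fasta"
        gff = out / "features.gff3"
        if not fasta.exists() or not gff.exists():
            raise InputError(
                "missing genome/annotation artifacts; run the simulate "
                "stage first or place genome.fasta + features.gff3 in the "
                "output directory")
        from .simulate import SyntheticDataset, SyntheticTruth

        genome = {k: v.residues for k, v in mio.read_fasta(fasta).items()}
        feats = read_gff3(gff)
        truth_path = out / "truth.json"
        truth = SyntheticTruth.from_json(truth_path) if truth_path.exists() \
            else SyntheticTruth({})
        state.dataset = SyntheticDataset(genome, feats, truth)
    return state.dataset


def _stage_fold(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    model = EnergyModel()
    profiles, shuffled, ensembles = {}, {}, {}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    for feat in dataset.features:
        seq = dataset.feature_sequence(feat)
        profiles[feat.feature_id] = window_scan(
            seq, model, cfg.window_size, cfg.step)
        shuffled[feat.feature_id] = [
            window_scan(shuffle_sequence(seq, int(rng.integers(2 ** 31))),
                        model, cfg.window_size, cfg.step)
            for _ in range(cfg.n_shuffles)]
        ensembles[feat.feature_id] = partition_function(seq, model)
    state.profiles, state.shuffled, state.ensembles = (profiles, shuffled,
                                                       ensembles)
    mio.write_window_mfe_tsv(profiles.values(), out / "window_mfe.tsv")
    for k in range(cfg.n_shuffles):
        mio.write_window_mfe_tsv(
            [shuffled[fid][k] for fid in profiles],
            out / f"window_mfe_shuffle{k}.tsv")
    mio.write_pair_prob_tsv(ensembles.values(), out / "pair_prob.tsv")


def _require_fold(cfg, out, state):
    if state.profiles is None:
        dataset = _require_dataset(cfg, out, state)
        lengths = {f.feature_id: f.length for f in dataset.features}
        state.profiles = mio.read_window_mfe_tsv(
            out / "window_mfe.tsv", cfg.window_size, lengths)
        state.shuffled = {fid: [] for fid in state.profiles}
        for k in range(cfg.n_shuffles):
            sh = mio.read_window_mfe_tsv(
                out / f"window_mfe_shuffle{k}.tsv", cfg.window_size, lengths)
            for fid in state.profiles:
                state.shuffled[fid].append(sh[fid])
        state.ensembles = mio.read_pair_prob_tsv(out / "pair_prob.tsv",
                                                 lengths)


def _stage_call(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_fold(cfg, out, state)
    threshold = cfg.mfe_threshold
    if cfg.engine == "builtin" and cfg.calibrate_threshold:
        pooled = [p for profs in state.shuffled.values() for p in profs]
        threshold = calibrate_mfe_threshold(pooled, cfg.calibrate_quantile)
    state.threshold = threshold
    summaries, regions, hairpins = summarize_structures(
        state.profiles, state.ensembles, state.shuffled,
        threshold=threshold, alpha=cfg.alpha,
        hairpin_params={"p_min": cfg.p_min, "min_span": cfg.min_span,
                        "max_mismatch": cfg.max_mismatch,
                        "max_asym": cfg.max_asym})
    feats = {f.feature_id: f for f in dataset.features}
    for fid, s in summaries.items():
        s.category = feats[fid].category
    state.summaries, state.regions, state.hairpins = (summaries, regions,
                                                      hairpins)
    rows = [(s.feature_id, s.category, s.length, s.min_mfe, s.mean_mfe,
             s.q, s.q_norm, s.has_low_window, s.p_raw, s.p_adj,
             s.rf_structured, s.n_lowmfe_regions, s.n_hairpins)
            for s in summaries.values()]
    pd.DataFrame(rows, columns=[
        "feature_id", "category", "length", "min_mfe", "mean_mfe", "q",
        "q_norm", "has_low_window", "p_raw", "p_adj", "rf_structured",
        "n_lowmfe", "n_hairpins"]).to_csv(
        out / "structure_summary.tsv", sep="\t", index=False)
    bed_rows = []
    for fid, regs in regions.items():
        f = feats[fid]
        for r in regs:
            gs, ge = f.to_genomic(r.start, r.end)
            bed_rows.append((f.chrom, gs, ge, fid,
                             int(min(1000, -r.min_window_mfe * 10)), f.strand))
    write_bed(sorted(bed_rows), out / "lowmfe.bed",
              f"lowMFE regions, threshold {threshold:.2f} kcal/mol")
    hp_rows = []
    for fid, hps in hairpins.items():
        f = feats[fid]
        for h in hps:
            gs, ge = f.to_genomic(h.start, h.end)
            hp_rows.append((f.chrom, gs, ge, fid,
                            int(h.mean_pair_prob * 1000), f.strand))
    write_bed(sorted(hp_rows), out / "hairpins.bed", "LP-hairpin arms")
    tallies = {}
    for s in summaries.values():
        t = tallies.setdefault(s.category, {"n": 0, "rf": 0, "hp": 0,
                                            "region_lengths": [],
                                            "hairpin_spans": []})
        t["n"] += 1
        t["rf"] += int(s.rf_structured)
        t["hp"] += int(s.n_hairpins > 0)
        t["region_lengths"] += [r.end - r.start for r in regions[s.feature_id]]
        t["hairpin_spans"] += [h.span for h in hairpins[s.feature_id]]
    report["threshold"] = threshold
    report["category_tallies"] = {
        cat: {"n_features": t["n"],
              "pct_rf_structured": round(100.0 * t["rf"] / t["n"], 2),
              "pct_with_hairpins": round(100.0 * t["hp"] / t["n"], 2),
              "median_lowmfe_length": (float(np.median(t["region_lengths"]))
                                       if t["region_lengths"] else None),
              "median_hairpin_span": (float(np.median(t["hairpin_spans"]))
                                      if t["hairpin_spans"] else None)}
        for cat, t in tallies.items()}


def _require_species(cfg, out, state):
    if state.species_tables is None:
        state.species_tables = {}
        for path in sorted(out.glob("smrna_*_*nt.tsv")):
            name = path.stem  # smrna_<lib>_<k>nt
            parts = name.split("_")
            lib, k = parts[1], int(parts[2][:-2])
            state.species_tables[(lib, k)] = mio.read_species_tsv(
                path, k, lib)
    if not state.species_tables:
        raise InputError("no smRNA species tables found; run simulate or "
                         "provide smrna_<lib>_<k>nt.tsv files")


def _stage_smrna(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_species(cfg, out, state)
    state.hits = {}
    rows = []
    for (lib, k), table in state.species_tables.items():
        hits = map_species_exact(table, dataset.genome)
        state.hits[(lib, k)] = hits
        for h in hits:
            rows.append((h.chrom, h.start, h.end, f"{lib}:{h.species}",
                         0, h.strand))
    write_bed(sorted(rows), out / "smrna_hits.bed", "exact-match smRNA hits")
    report["n_hits"] = len(rows)


def _structured_regions_genomic(cfg, state, feats):
    src = state.regions if cfg.skew_regions == "lowmfe" else state.hairpins
    out = {}
    for fid, items in src.items():
        f = feats[fid]
        ivs = []
        for it in items:
            gs, ge = f.to_genomic(it.start, it.end)
            ivs.append((gs, ge))
        if ivs:
            out[fid] = sorted(ivs)
    return out


def _require_call(cfg, out, state):
    if state.regions is None:
        _stage_call(cfg, out, state, {})


def _stage_skew(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_call(cfg, out, state)
    if state.hits is None:
        _stage_smrna(cfg, out, state, {})
    feats = {f.feature_id: f for f in dataset.features}
    regions = _structured_regions_genomic(cfg, state, feats)
    records = []
    for (lib, k), hits in state.hits.items():
        by_chrom: dict[str, list] = {}
        for h in hits:
            by_chrom.setdefault(h.chrom, []).append(h)
        for fid, ivs in regions.items():
            f = feats[fid]
            rec = compute_skew(fid, f.chrom, f.start, f.end, ivs,
                               by_chrom.get(f.chrom, []), lib, k)
            records.append(rec)
    state.skew_records = records
    skew_frame(records).to_csv(out / "skew.tsv", sep="\t", index=False)
    summary = {}
    for k in sorted({r.length_class for r in records}):
        for cat in sorted({feats[r.feature_id].category for r in records}):
            vals = [r.skew for r in records
                    if r.length_class == k and not r.dropped
                    and feats[r.feature_id].category == cat]
            if vals:
                entry = {"n": len(vals),
                         "mean_skew": round(float(np.mean(vals)), 4)}
                if len(vals) >= 5 and any(v != 0 for v in vals):
                    entry["sign_test_p"] = skew_sign_test(vals)
                summary[f"{cat}_{k}nt"] = entry
    report["skew_summary"] = summary


def _stage_methprofile(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_call(cfg, out, state)
    if state.methylome is None:
        state.methylome = mio.read_methylation_tsv(out / "methylation.tsv")
    feats = {f.feature_id: f for f in dataset.features}
    regions = _structured_regions_genomic(cfg, state, feats)
    chrom_lengths = {c: len(s) for c, s in dataset.genome.items()}
    region_list, control_list = [], []
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12]))
    for fid, ivs in regions.items():
        f = feats[fid]
        for gs, ge in ivs:
            region_list.append((f.chrom, gs, ge))
            ctrl = draw_control_window(f.start, f.end, gs, ge,
                                       int(rng.integers(2 ** 31)),
                                       all_regions=ivs)
            if ctrl is not None:
                control_list.append((f.chrom, ctrl[0], ctrl[1]))
    if not region_list:
        report["metaprofile"] = None
        return
    prof = methylation_metaprofile(
        region_list, state.methylome, chrom_lengths, cfg.flank,
        cfg.meth_window, context="CHH",
        control_regions=control_list or None)
    prof.frame().to_csv(out / "metaprofile_chh.tsv", sep="\t", index=False)
    report["metaprofile"] = {
        "n_regions": len(region_list),
        "n_controls": len(control_list),
        "center_level": float(prof.mean_level[prof.n_flank_windows // 2]),
        "center_vs_flank_p": prof.center_vs_flank_p,
    }


def _stage_landscape(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_call(cfg, out, state)
    rows = []
    by_cat: dict[str, list] = {}
    for f in dataset.features:
        by_cat.setdefault(f.category, []).append(f)
    for cat, feats in sorted(by_cat.items()):
        triples = [(f.feature_id, f.length, f.strand) for f in feats]
        regs = {f.feature_id: [(r.start, r.end)
                               for r in state.regions.get(f.feature_id, [])]
                for f in feats}
        counts = feature_landscape(triples, regs, cfg.bins)
        for b, c in enumerate(counts, start=1):
            rows.append((cat, b, int(c)))
    pd.DataFrame(rows, columns=["category", "bin", "count"]) \
        .to_csv(out / "landscape.tsv", sep="\t", index=False)


def _stage_enrich(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_call(cfg, out, state)
    feats = {f.feature_id: f for f in dataset.features}
    items = []
    for fid, hps in state.hairpins.items():
        f = feats[fid]
        for h in hps:
            gs, ge = f.to_genomic(h.start, h.end)
            items.append((f.chrom, gs, ge))
    targets = []
    for fid, regs in state.regions.items():
        f = feats[fid]
        for r in regs:
            gs, ge = f.to_genomic(r.start, r.end)
            targets.append((f.chrom, gs, ge))
    space = {"features": sum(f.length for f in dataset.features)}
    if not items:
        report["hairpin_in_lowmfe"] = None
        return
    res = overlap_enrichment(items, targets, space)
    pd.DataFrame([{
        "items": "hairpins", "targets": "lowmfe_regions",
        "n_items": res.n_items, "observed": res.observed_overlapping,
        "expected": res.expected_overlapping,
        "covered_fraction": res.covered_fraction, "fold": res.fold,
    }]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report["hairpin_in_lowmfe"] = {
        "n_items": res.n_items, "observed": res.observed_overlapping,
        "expected": round(res.expected_overlapping, 3),
        "fold": (round(res.fold, 3) if np.isfinite(res.fold) else None)}


def _stage_expression(cfg, out, state, report):
    dataset = _require_dataset(cfg, out, state)
    _require_call(cfg, out, state)
    if state.tissue_expr is None:
        state.tissue_expr = pd.read_csv(out / "expression_tissues.tsv",
                                        sep="\t", index_col=0)
        state.line_expr = pd.read_csv(out / "expression_lines.tsv",
                                      sep="\t", index_col=0)
    genes = [f for f in dataset.features if f.category == "gene"]
    gene_ids = [g.feature_id for g in genes if g.feature_id
                in state.tissue_expr.index]
    if len(gene_ids) < 8:
        report["expression"] = None
        return
    structured = np.array([state.summaries[g].rf_structured
                           for g in gene_ids])
    combined = state.tissue_expr.loc[gene_ids].mean(axis=1).to_numpy()
    cvs = cv_frame(state.line_expr.loc[gene_ids])
    dens = _gene_density_from_tables(
        dataset, state.species_tables or {})
    density = np.array([dens.get(g, 0.0) for g in gene_ids])
    min_mfe = np.array([state.summaries[g].min_mfe for g in gene_ids])
    result = {}
    if structured.any() and (~structured).any():
        result["expression_contrast"] = compare_structured_expression(
            combined, structured, n_perm=2000, seed=cfg.seed)
    try:
        result["cv_models"] = fit_cv_models(
            cvs["cv"].to_numpy(), smrna_density=density, min_mfe=min_mfe,
            b73_expression=combined)
    except InputError:
        result["cv_models"] = None
    q = quartile_smrna_summary(min_mfe, density)
    q.to_csv(out / "quartile_smrna.tsv", sep="\t", index=False)
    cvs.to_csv(out / "cv.tsv", sep="\t")
    result["quartile_mean_density"] = q["mean_smrna_count"].tolist()
    report["expression"] = result


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fold": _stage_fold,
    "call": _stage_call,
    "smrna": _stage_smrna,
    "skew": _stage_skew,
    "methprofile": _stage_methprofile,
    "landscape": _stage_landscape,
    "enrich": _stage_enrich,
    "expression": _stage_expression,
}
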