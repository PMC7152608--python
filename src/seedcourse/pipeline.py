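"""End-to-end orchestration: simulate -> qc -> de -> patterns -> gcoe ->
h2 -> sizetest -> metabolites.

Every stage reads and writes plain TSV files inside one output
directory, records content checksums in ``manifest.json`` and is
skipped on re-runs when its inputs and outputs are unchanged (delete a
stage's outputs to force it, and everything downstream whose inputs
then change, to re-run).  All randomness flows from one integer seed,
split deterministically per stage by hashing the stage name, so
changing one stage's permutation count does not perturb another
stage's draws.
"""
from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_size, diffexpr, gcoe, genetics, metabolites, patterns, qc
from .containers import (CountMatrix, ensure_dir, read_counts, read_grm,
                         read_matrix, sha256_file, write_counts, write_grm,
                         write_matrix)
from .simulate import (StudyDesign, make_truth, simulate_counts,
                       simulate_markers, simulate_metabolites)

log = logging.getLogger("seedcourse")

STAGES = ["simulate", "qc", "de", "patterns", "gcoe", "h2", "sizetest",
          "metabolites"]


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    Serialized verbatim (YAML mapping) into the output directory;
    unknown keys in a config file are rejected.
    """

    seed: int = 1
    output_dir: str = "seedcourse_run"

    # --- synthetic study -------------------------------------------------
    n_transcripts: int = 1000
    n_lines: int = 22
    time_points: list = field(default_factory=lambda: [8, 13, 18, 23, 28, 33])
    n_locations: int = 2
    n_reps: int = 2
    missing_fraction: float = 109 / 528
    n_markers: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5
    step_log2: float = 1.0
    line_sd: float = 0.5
    latent_sd: float = 0.5
    depth_low: float = 0.5
    depth_high: float = 2.0
    h2_module: float = 0.8
    modules_per_pattern: int = 2
    n_metabolites: int = 100
    linked_fraction: float = 0.3
    metab_beta: float = 1.0

    # --- qc ---------------------------------------------------------------
    min_mapped: int = -1          # -1: auto-scale 500000 * n_transcripts/59815
    min_count: int = 2
    min_samples: int = 10
    top_n: int = 500
    min_minor_fraction: float = 0.05
    min_silhouette: float = 0.65

    # --- differential expression -----------------------------------------
    alpha_de: float = 0.05
    alpha_interaction: float = 0.1

    # --- patterns ---------------------------------------------------------
    n_perm_patterns: int = 1000
    top_k: int = 20

    # --- gcoe / h2 ---------------------------------------------------------
    k_min: int = 4
    k_max: int = 20
    linkage: str = "ward"
    lam: float = 1.0
    n_tcoe_sets: int = 22
    n_perm_h2: int = 50

    # --- cluster-size test --------------------------------------------------
    k_test: int = 8
    n_perm_sizetest: int = 1000

    # --- metabolites ---------------------------------------------------------
    h2_threshold: float = 0.4
    n_perm_metab: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def design(self) -> StudyDesign:
        return StudyDesign(self.n_lines, tuple(self.time_points),
                           self.n_locations, self.n_reps,
                           self.missing_fraction)

    def effective_min_mapped(self) -> int:
        if self.min_mapped >= 0:
            return self.min_mapped
        return int(round(500_000 * self.n_transcripts / 59_815))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (kept below 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# stage implementations (file-level contracts)
# ---------------------------------------------------------------------------

STAGE_OUTPUTS = {
    "simulate": ["counts.tsv", "metadata.tsv", "grm.tsv", "metabolites.tsv",
                 "truth_patterns.tsv", "truth_links.tsv"],
    "qc": ["qc_counts.tsv", "qc_metadata.tsv", "size_factors.tsv",
           "normalized_all.tsv", "normalized_major.tsv", "pca_scores.tsv",
           "outlier_samples.txt"],
    "de": ["interaction_screen.tsv", "de_results.tsv"],
    "patterns": ["pattern_codes.tsv", "pattern_table.tsv",
                 "pattern_null_summary.tsv"],
    "gcoe": ["lsmeans.tsv", "gcoe_membership.tsv", "pc1_scores.tsv",
             "gcoe_k.tsv"],
    "h2": ["h2_results.tsv", "h2_permutation.tsv"],
    "sizetest": ["cluster_size_test.tsv"],
    "metabolites": ["metabolite_h2.tsv", "metabolite_regression.tsv",
                    "metabolite_null_summary.tsv"],
}

STAGE_INPUTS = {
    "simulate": [],
    "qc": ["counts.tsv", "metadata.tsv"],
    "de": ["qc_counts.tsv", "qc_metadata.tsv", "outlier_samples.txt"],
    "patterns": ["de_results.tsv"],
    "gcoe": ["normalized_all.tsv", "qc_metadata.tsv", "pattern_codes.tsv",
             "grm.tsv"],
    "h2": ["lsmeans.tsv", "gcoe_membership.tsv", "pc1_scores.tsv", "grm.tsv",
           "gcoe_k.tsv"],
    "sizetest": ["lsmeans.tsv", "pattern_codes.tsv"],
    "metabolites": ["metabolites.tsv", "pc1_scores.tsv"],
}


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    design = cfg.design()
    seed = stage_seed(cfg.seed, "simulate")
    markers = simulate_markers(design.n_lines, cfg.n_markers,
                               (cfg.maf_low, cfg.maf_high), seed)
    grm = genetics.grm_vanraden(markers)
    truth = make_truth(design, cfg.n_transcripts,
                       modules_per_pattern=cfg.modules_per_pattern,
                       h2=cfg.h2_module, grm=grm, seed=seed + 1)
    cm, md = simulate_counts(design, truth, (cfg.depth_low, cfg.depth_high),
                             seed + 2, cfg.step_log2, cfg.line_sd,
                             cfg.latent_sd)
    # metabolite links: a fraction tied to the most populous modules
    rng = np.random.default_rng(seed + 3)
    module_keys = sorted(truth.line_values)
    links = []
    n_linked = int(round(cfg.linked_fraction * cfg.n_metabolites))
    for i in range(cfg.n_metabolites):
        if i < n_linked and module_keys:
            key = module_keys[i % len(module_keys)]
            beta = cfg.metab_beta * (1 if rng.random() < 0.5 else -1)
        else:
            key = module_keys[0] if module_keys else ("00000", 1)
            beta = 0.0
        links.append((f"met{i + 1:04d}", key[0], key[1], beta))
    truth.metabolite_links = pd.DataFrame(
        links, columns=["metabolite", "tcoe_id", "gcoe_id", "beta"])
    pc1_truth = {k: v for k, v in truth.line_values.items()}
    met = simulate_metabolites(truth, pc1_truth, design, seed=seed + 4)

    write_counts(cm, out / "counts.tsv", out / "metadata.tsv")
    write_grm(grm, out / "grm.tsv")
    met.to_csv(out / "metabolites.tsv", sep="\t", index=False)
    truth_df = truth.modules.copy()
    truth_df.insert(0, "pattern", truth.patterns)
    truth_df["dispersion"] = truth.dispersion
    truth_df["latent_loading"] = truth.latent_loadings
    truth_df.to_csv(out / "truth_patterns.tsv", sep="\t",
                    index_label="transcript_id")
    truth.metabolite_links.to_csv(out / "truth_links.tsv", sep="\t",
                                  index=False)


def _stage_qc(cfg: RunConfig, out: Path) -> None:
    cm = read_counts(out / "counts.tsv", out / "metadata.tsv")
    cm = qc.filter_samples(cm, cfg.effective_min_mapped())
    cm = qc.filter_transcripts(cm, cfg.min_count, cfg.min_samples)
    sf = qc.size_factors(cm)
    nm = qc.variance_stabilize(cm, sf)
    scores, _ = qc.sample_pca(nm, min(cfg.top_n, cm.n_transcripts))
    major, minor = qc.split_outlier_cluster(
        scores, cfg.min_minor_fraction, cfg.min_silhouette,
        random_state=stage_seed(cfg.seed, "qc") % (2 ** 31))
    write_counts(cm, out / "qc_counts.tsv", out / "qc_metadata.tsv")
    sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t",
                         index_label="sample_id")
    write_matrix(nm.values, out / "normalized_all.tsv", "transcript_id")
    write_matrix(nm.values.loc[:, list(major)], out / "normalized_major.tsv",
                 "transcript_id")
    write_matrix(scores, out / "pca_scores.tsv", "sample_id")
    (out / "outlier_samples.txt").write_text("\n".join(minor) + "\n")


def _stage_de(cfg: RunConfig, out: Path) -> None:
    cm = read_counts(out / "qc_counts.tsv", out / "qc_metadata.tsv")
    minor = [s for s in (out / "outlier_samples.txt").read_text().split()
             if s]
    major = [s for s in cm.sample_ids if s not in set(minor)]
    cm = cm.subset_samples(major)
    cm = qc.filter_transcripts(cm, cfg.min_count,
                               min(cfg.min_samples, cm.n_samples))
    sf = qc.size_factors(cm)
    disp = diffexpr.estimate_dispersions(cm, sf)
    screen = diffexpr.interaction_lrt(cm, sf, cfg.alpha_interaction, disp)
    screen.to_csv(out / "interaction_screen.tsv", sep="\t")
    keep = screen.index[~screen["flagged"].fillna(False)]
    cm = cm.subset_transcripts(keep)
    tables = diffexpr.adjacent_contrasts(cm, sf, cfg.alpha_de,
                                         disp.loc[keep])
    frames = []
    for lab, tab in tables.items():
        tab = tab.reset_index()
        tab.insert(1, "contrast", lab)
        frames.append(tab)
    pd.concat(frames, ignore_index=True).to_csv(out / "de_results.tsv",
                                                sep="\t", index=False)


def _stage_patterns(cfg: RunConfig, out: Path) -> None:
    de = pd.read_csv(out / "de_results.tsv", sep="\t")
    tables = {lab: sub.set_index("transcript_id")
              for lab, sub in de.groupby("contrast", sort=False)}
    # keep chronological interval order
    order = sorted(tables, key=lambda s: float(s.split("-")[0]))
    codes = patterns.encode_patterns({lab: tables[lab] for lab in order},
                                     cfg.alpha_de)
    table, theoretical = patterns.enumerate_patterns(codes)
    null = patterns.permutation_null(codes, cfg.n_perm_patterns, cfg.top_k,
                                     stage_seed(cfg.seed, "patterns"))
    codes.to_frame().to_csv(out / "pattern_codes.tsv", sep="\t",
                            index_label="transcript_id")
    table.to_csv(out / "pattern_table.tsv", sep="\t", index=False)
    summary = null.summary()
    summary["theoretical_patterns"] = theoretical
    summary.to_csv(out / "pattern_null_summary.tsv", sep="\t", index=False)


def _eligible_sets(table: pd.DataFrame, codes: pd.Series, cfg: RunConfig
                   ) -> dict:
    """Top TCoE sets large enough to subcluster."""
    sets = {}
    for row in table.itertuples():
        if len(sets) >= cfg.n_tcoe_sets:
            break
        members = codes.index[codes == row.code]
        if len(members) >= max(cfg.k_min + 1, 4):
            sets[row.code] = list(members)
    return sets


def _stage_gcoe(cfg: RunConfig, out: Path) -> None:
    values = read_matrix(out / "normalized_all.tsv")
    md = pd.read_csv(out / "qc_metadata.tsv", sep="\t", index_col=0)
    sf = pd.read_csv(out / "size_factors.tsv", sep="\t", index_col=0)
    from .containers import NormalizedMatrix

    nm = NormalizedMatrix(values, sf.iloc[:, 0], md)
    adj = gcoe.adjust_latent(nm)
    lsm = gcoe.lsmeans(adj.adjusted)
    write_matrix(lsm, out / "lsmeans.tsv", "line")

    codes = pd.read_csv(out / "pattern_codes.tsv", sep="\t",
                        index_col=0)["pattern"]
    codes = codes[codes.index.isin(lsm.columns)]
    table, _ = patterns.enumerate_patterns(codes)
    grm = read_grm(out / "grm.tsv")
    sets = _eligible_sets(table, codes, cfg)

    member_rows, pc1_cols, k_rows = [], {}, []
    for tcoe_id, members in sets.items():
        k_range = range(cfg.k_min, min(cfg.k_max, len(members) - 1) + 1)
        k, _summary = gcoe.choose_k(lsm, members, grm, k_range, cfg.lam,
                                    cfg.linkage)
        k_rows.append((tcoe_id, len(members), k))
        labels = gcoe.subcluster(lsm, members, k, cfg.linkage)
        for g in sorted(labels.unique()):
            mem = labels.index[labels == g]
            scores, varexp = gcoe.pc1_scores(lsm, mem)
            pc1_cols[f"{tcoe_id}|{g}"] = scores
            for t in mem:
                member_rows.append((tcoe_id, int(g), t))
    pd.DataFrame(member_rows,
                 columns=["tcoe_id", "gcoe_id", "transcript_id"]
                 ).to_csv(out / "gcoe_membership.tsv", sep="\t", index=False)
    pd.DataFrame(pc1_cols, index=lsm.index).to_csv(
        out / "pc1_scores.tsv", sep="\t", index_label="line")
    pd.DataFrame(k_rows, columns=["tcoe_id", "n_members", "k"]).to_csv(
        out / "gcoe_k.tsv", sep="\t", index=False)


def _stage_h2(cfg: RunConfig, out: Path) -> None:
    lsm = read_matrix(out / "lsmeans.tsv")
    grm = read_grm(out / "grm.tsv")
    pc1 = read_matrix(out / "pc1_scores.tsv")
    membership = pd.read_csv(out / "gcoe_membership.tsv", sep="\t")
    kk = pd.read_csv(out / "gcoe_k.tsv", sep="\t")
    rows = []
    for col in pc1.columns:
        tcoe_id, g = col.rsplit("|", 1)
        est = genetics.estimate_h2(pc1[col], grm)
        rows.append((tcoe_id, int(g), est.sigma_u2, est.sigma_e2, est.h2,
                     est.lrt_stat, est.p))
    pd.DataFrame(rows, columns=["tcoe_id", "gcoe_id", "sigma_u2", "sigma_e2",
                                "h2", "lrt_stat", "p"]
                 ).to_csv(out / "h2_results.tsv", sep="\t", index=False)
    sets = {}
    for row in kk.itertuples():
        members = membership.loc[membership["tcoe_id"] == row.tcoe_id,
                                 "transcript_id"]
        sets[row.tcoe_id] = (list(members), int(row.k))
    null = genetics.h2_permutation_null(lsm, sets, grm, cfg.n_perm_h2,
                                        stage_seed(cfg.seed, "h2"))
    null.to_csv(out / "h2_permutation.tsv", sep="\t", index=False)


def _stage_sizetest(cfg: RunConfig, out: Path) -> None:
    lsm = read_matrix(out / "lsmeans.tsv")
    codes = pd.read_csv(out / "pattern_codes.tsv", sep="\t",
                        index_col=0)["pattern"]
    codes = codes[codes.index.isin(lsm.columns)]
    table, _ = patterns.enumerate_patterns(codes)
    seed = stage_seed(cfg.seed, "sizetest")
    rows = []
    n_set = 0
    for row in table.itertuples():
        if n_set >= cfg.n_tcoe_sets:
            break
        members = codes.index[codes == row.code]
        if len(members) < cfg.k_test + 1:
            continue
        n_set += 1
        res = cluster_size.mahalanobis_test(lsm, members, cfg.k_test,
                                            cfg.n_perm_sizetest,
                                            seed + n_set)
        rows.append((row.code, len(members), res.d2, res.df, res.p))
    tab = pd.DataFrame(rows, columns=["tcoe_id", "n_members", "D2", "df", "p"])
    if len(tab):
        tab["bonferroni_significant"] = cluster_size.bonferroni_screen(
            tab["p"].to_numpy())
    tab.to_csv(out / "cluster_size_test.tsv", sep="\t", index=False)


def _stage_metabolites(cfg: RunConfig, out: Path) -> None:
    met = pd.read_csv(out / "metabolites.tsv", sep="\t")
    pc1 = read_matrix(out / "pc1_scores.tsv")
    h2 = metabolites.metabolite_h2_table(met)
    h2.to_frame().to_csv(out / "metabolite_h2.tsv", sep="\t")
    kept = metabolites.filter_heritable(met, h2, cfg.h2_threshold)
    if kept.empty or pc1.shape[1] == 0:
        pd.DataFrame(columns=["metabolite", "gcoe", "slope", "t", "p"]).to_csv(
            out / "metabolite_regression.tsv", sep="\t", index=False)
        pd.DataFrame().to_csv(out / "metabolite_null_summary.tsv", sep="\t")
        return
    lines = metabolites.line_means(kept)
    comp = metabolites.permutation_compare(lines, pc1, cfg.n_perm_metab,
                                           stage_seed(cfg.seed, "metabolites"))
    comp.observed.to_csv(out / "metabolite_regression.tsv", sep="\t",
                         index=False)
    summary = comp.per_module.copy()
    summary["ranksum_stat"] = comp.ranksum_stat
    summary["ranksum_p"] = comp.ranksum_p
    summary.to_csv(out / "metabolite_null_summary.tsv", sep="\t", index=False)


STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "de": _stage_de,
    "patterns": _stage_patterns,
    "gcoe": _stage_gcoe,
    "h2": _stage_h2,
    "sizetest": _stage_sizetest,
    "metabolites": _stage_metabolites,
}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _checksums(out: Path, names) -> dict:
    return {n: sha256_file(out / n) for n in names if (out / n).exists()}


def run_pipeline(cfg: RunConfig, stages=None, force: bool = False) -> dict:
    """Run (or resume) the pipeline; returns the manifest dictionary."""
    out = ensure_dir(cfg.output_dir)
    cfg.to_yaml(out / "config.yaml")
    manifest_path = out / "manifest.json"
    manifest = {"seed": cfg.seed, "stages": {}}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest["seed"] = cfg.seed
    stages = list(stages) if stages is not None else list(STAGES)
    for name in stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")

    for name in STAGES:
        if name not in stages:
            continue
        t0 = time.perf_counter()
        missing = [f for f in STAGE_INPUTS[name] if not (out / f).exists()]
        if missing:
            producer = {f: s for s, outs in STAGE_OUTPUTS.items()
                        for f in outs}
            need = sorted({producer[f] for f in missing})
            raise FileNotFoundError(
                f"stage {name!r} is missing inputs {missing}; "
                f"(re)run stage(s) {need}")
        inputs = _checksums(out, STAGE_INPUTS[name])
        prior = manifest["stages"].get(name, {})
        outputs_exist = all((out / f).exists() for f in STAGE_OUTPUTS[name])
        unchanged = (outputs_exist and not force
                     and prior.get("inputs") == inputs
                     and prior.get("outputs") == _checksums(
                         out, STAGE_OUTPUTS[name]))
        if unchanged:
            log.info("stage=%s seed=%d status=skipped", name, cfg.seed)
            manifest["stages"][name]["status"] = "skipped"
            continue
        log.info("stage=%s seed=%d status=running", name, cfg.seed)
        STAGE_FN[name](cfg, out)
        elapsed = time.perf_counter() - t0
        manifest["stages"][name] = {
            "inputs": inputs,
            "outputs": _checksums(out, STAGE_OUTPUTS[name]),
            "status": "run",
            "elapsed_s": round(elapsed, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.info("stage=%s seed=%d elapsed=%.2fs", name, cfg.seed, elapsed)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def validate_inputs(counts_path, metadata_path, grm_path=None,
                    metabolites_path=None) -> list:
    """Cross-check IDs and types across the pipeline's input files.

    Returns a list of problem descriptions (empty when all checks pass).
    """
    problems: list[str] = []
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    md = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = counts.columns.difference(md.index.astype(str))
    if len(missing):
        problems.append(f"samples absent from metadata: {sorted(missing)}")
    for col in ("line", "location", "replicate", "daa"):
        if col not in md.columns:
            problems.append(f"metadata lacks column {col!r}")
    arr = counts.to_numpy()
    frac = np.modf(arr.astype(float))[0]
    bad = np.argwhere(frac != 0)
    if bad.size:
        i, j = bad[0]
        problems.append(
            f"non-integer count at transcript {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}")
    if (arr < 0).any():
        problems.append("negative counts present")

    lines = set(md["line"].astype(str)) if "line" in md.columns else set()
    if grm_path is not None:
        try:
            grm = read_grm(grm_path)
            absent = sorted(lines - set(grm.index))
            if absent:
                problems.append(f"lines absent from GRM: {absent}")
        except ValueError as exc:
            problems.append(str(exc))
    if metabolites_path is not None:
        met = pd.read_csv(metabolites_path, sep="\t")
        for col in ("metabolite", "line", "location", "replicate", "value"):
            if col not in met.columns:
                problems.append(f"metabolite table lacks column {col!r}")
        if "line" in met.columns:
            absent = sorted(set(met["line"].astype(str)) - lines)
            if absent:
                problems.append(f"metabolite lines absent from metadata: "
                                f"{absent}")
    return problems
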