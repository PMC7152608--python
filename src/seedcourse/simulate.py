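"""Synthetic study generator with known ground truth.

Emulates the structure of a seed-development expression study: a diversity
panel of inbred lines sampled over a six-point developmental time course
(days after anthesis) at two locations with two replicates, 3'-tag RNA-seq
counts, a marker-derived genomic relationship matrix (GRM) that is close to
diagonal, and mature-seed metabolites measured once per line x location x
replicate plot.

The generative model mirrors the analysis assumptions:

* counts are negative binomial with a per-sample depth (size) factor and a
  per-transcript dispersion;
* each transcript's log2 mean follows its assigned temporal pattern code
  (one character per adjacent time interval, ``u``/``d``/``0``);
* transcripts belong to modules; within a module, per-line offsets share a
  genetic component (drawn against the GRM, variance fraction
  ``h2_module``) plus transcript-specific line noise;
* one latent batch factor loads on a subset of transcripts;
* metabolites are linear in a module's per-line PC1 signal plus design
  (location, location x line, replication) noise.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

PATTERN_ALPHABET = ("u", "d", "0")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the study.

    Defaults are the full design of the emulated study: 22 lines x
    6 time points x 2 locations x 2 replicates = 528 potential samples,
    of which a fraction goes missing in the field (109/528 by default).
    """

    n_lines: int = 22
    time_points: tuple = (8, 13, 18, 23, 28, 33)
    n_locations: int = 2
    n_reps: int = 2
    missing_fraction: float = 109 / 528

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_locations < 1 or self.n_reps < 1:
            raise ValueError("design factors must be positive")
        tp = tuple(self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    @property
    def n_intervals(self) -> int:
        return self.n_times - 1

    @property
    def potential_samples(self) -> int:
        return self.n_lines * self.n_times * self.n_locations * self.n_reps

    @property
    def lines(self) -> list:
        width = len(str(self.n_lines))
        return [f"L{str(i + 1).zfill(width)}" for i in range(self.n_lines)]

    @property
    def interval_labels(self) -> list:
        tp = self.time_points
        return [f"{a}-{b}" for a, b in zip(tp, tp[1:])]


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated study.

    ``patterns`` maps transcript -> pattern code; ``modules`` maps
    transcript -> (tcoe_id, gcoe_id); ``line_values`` holds one per-line
    genetic-value vector per module key ``(tcoe_id, gcoe_id)``;
    ``h2_module`` the intended genetic variance fraction of each module's
    line offsets; ``metabolite_links`` rows (metabolite, tcoe_id, gcoe_id,
    beta); ``dispersion`` and ``latent_loadings`` are per transcript.
    """

    patterns: pd.Series
    modules: pd.DataFrame
    line_values: dict
    h2_module: dict
    dispersion: pd.Series
    latent_loadings: pd.Series
    metabolite_links: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["metabolite", "tcoe_id", "gcoe_id", "beta"]))

    def __post_init__(self) -> None:
        if self.patterns.isna().any():
            raise ValueError("every transcript must have a pattern code")
        for key, h2 in self.h2_module.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2_module[{key}] outside [0, 1]")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.patterns.index


# ---------------------------------------------------------------------------
# markers and GRM
# ---------------------------------------------------------------------------

def simulate_markers(n_lines: int, n_markers: int,
                     maf_range: tuple = (0.05, 0.5), seed: int = 0
                     ) -> pd.DataFrame:
    """Independent biallelic dosages (0/1/2) for unrelated inbred-ish lines.

    Allele frequencies are uniform on ``maf_range``; markers are
    independent, so the derived GRM approaches a diagonal matrix as the
    marker count grows.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_markers < n_lines:
        raise ValueError("need at least as many markers as lines")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    dosages = rng.binomial(2, p[None, :], size=(n_lines, n_markers))
    width = len(str(n_lines))
    lines = [f"L{str(i + 1).zfill(width)}" for i in range(n_lines)]
    cols = [f"M{j + 1}" for j in range(n_markers)]
    return pd.DataFrame(dosages, index=lines, columns=cols)


def structured_grm(n_lines: int, n_families: int = 5,
                   relatedness: float = 0.5) -> pd.DataFrame:
    """Block relationship matrix with family structure.

    Lines fall into ``n_families`` groups with within-family
    relatedness ``relatedness`` and unit diagonal.  The spread-out
    eigenvalue spectrum of such a matrix makes the genetic and residual
    variances of a per-line trait well identified, which is what
    "genetically structured" power experiments need; contrast with the
    near-diagonal GRM of a deliberately unrelated diversity panel.
    """
    if not 0.0 <= relatedness < 1.0:
        raise ValueError("relatedness must be in [0, 1)")
    if not 1 <= n_families <= n_lines:
        raise ValueError("need 1 <= n_families <= n_lines")
    sizes = [n_lines // n_families + (1 if i < n_lines % n_families else 0)
             for i in range(n_families)]
    K = np.zeros((n_lines, n_lines))
    i0 = 0
    for s in sizes:
        K[i0:i0 + s, i0:i0 + s] = relatedness
        i0 += s
    np.fill_diagonal(K, 1.0)
    width = len(str(n_lines))
    lines = [f"L{str(i + 1).zfill(width)}" for i in range(n_lines)]
    return pd.DataFrame(K, index=lines, columns=lines)


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _chol_psd(K: np.ndarray) -> np.ndarray:
    # Cholesky with a tiny jitter so marker-derived (PSD up to rounding)
    # matrices always factor.
    n = K.shape[0]
    jitter = 1e-8 * np.trace(K) / n
    for _ in range(6):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 10
    raise np.linalg.LinAlgError("relationship matrix is not PSD")


def make_truth(design: StudyDesign, n_transcripts: int,
               pattern_codes=None, modules_per_pattern: int = 1,
               h2: float = 0.8, grm: pd.DataFrame | None = None,
               dispersion_range: tuple = (0.01, 1.0),
               latent_fraction: float = 0.3, seed: int = 0
               ) -> SimulationTruth:
    """Assemble a :class:`SimulationTruth` with sensible defaults.

    ``pattern_codes`` may be a list of codes to recycle over transcripts;
    by default codes are drawn uniformly over the per-interval alphabet.
    Each (pattern, module) pair receives its own per-line genetic value
    vector drawn against ``grm`` (identity if omitted) with variance
    ``h2`` relative to a unit total line variance.
    """
    rng = np.random.default_rng(seed)
    k = design.n_intervals
    tx = pd.Index([f"T{str(i + 1).zfill(len(str(n_transcripts)))}"
                   for i in range(n_transcripts)], name="transcript_id")
    if pattern_codes is None:
        chars = rng.choice(PATTERN_ALPHABET, size=(n_transcripts, k))
        codes = ["".join(row) for row in chars]
    else:
        codes = [pattern_codes[i % len(pattern_codes)]
                 for i in range(n_transcripts)]
    patterns = pd.Series(codes, index=tx, name="pattern")

    gcoe_ids = rng.integers(1, modules_per_pattern + 1, size=n_transcripts)
    modules = pd.DataFrame({"tcoe_id": codes, "gcoe_id": gcoe_ids}, index=tx)

    if grm is None:
        L = np.eye(design.n_lines)
    else:
        L = _chol_psd(grm.to_numpy(float))
    line_values: dict = {}
    h2_module: dict = {}
    for key in sorted(set(zip(codes, gcoe_ids))):
        u = L @ rng.standard_normal(design.n_lines)
        sd = u.std()
        line_values[key] = u / sd * np.sqrt(h2) if sd > 0 else u
        h2_module[key] = h2

    dispersion = pd.Series(
        np.exp(rng.uniform(np.log(dispersion_range[0]),
                           np.log(dispersion_range[1]), n_transcripts)),
        index=tx, name="dispersion")
    loadings = np.zeros(n_transcripts)
    n_latent = int(round(latent_fraction * n_transcripts))
    idx = rng.choice(n_transcripts, size=n_latent, replace=False)
    loadings[idx] = rng.standard_normal(n_latent)
    latent_loadings = pd.Series(loadings, index=tx, name="latent_loading")

    return SimulationTruth(patterns=patterns, modules=modules,
                           line_values=line_values, h2_module=h2_module,
                           dispersion=dispersion,
                           latent_loadings=latent_loadings)


def sample_table(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Full factorial sample metadata, minus the missing fraction."""
    rows = []
    for line, daa, loc, rep in itertools.product(
            design.lines, design.time_points,
            range(1, design.n_locations + 1), range(1, design.n_reps + 1)):
        rows.append((line, f"S{loc}", rep, daa))
    md = pd.DataFrame(rows, columns=["line", "location", "replicate", "daa"])
    md.index = pd.Index(
        [f"{r.line}_{r.daa}DAA_{r.location}_R{r.replicate}"
         for r in md.itertuples()], name="sample_id")
    n_drop = int(round(design.missing_fraction * len(md)))
    if n_drop:
        drop = rng.choice(len(md), size=n_drop, replace=False)
        md = md.drop(md.index[drop])
    return md


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _pattern_profile(code: str, step_log2: float, n_times: int) -> np.ndarray:
    if len(code) != n_times - 1:
        raise ValueError(
            f"pattern {code!r} has length {len(code)}, expected {n_times - 1}")
    prof = np.zeros(n_times)
    for i, ch in enumerate(code):
        if ch == "u":
            prof[i + 1] = prof[i] + step_log2
        elif ch == "d":
            prof[i + 1] = prof[i] - step_log2
        elif ch == "0":
            prof[i + 1] = prof[i]
        else:
            raise ValueError(f"invalid pattern character {ch!r} in {code!r}")
    return prof


def simulate_counts(design: StudyDesign, truth: SimulationTruth,
                    depth_range: tuple = (0.5, 2.0), seed: int = 0,
                    step_log2: float = 1.0, line_sd: float = 0.5,
                    latent_sd: float = 0.5, resid_sd: float = 0.0,
                    base_log2_range: tuple = (3.0, 8.0)):
    """Draw a :class:`CountMatrix` plus metadata from the truth object.

    ``depth_range`` bounds the log-uniform per-sample depth factors;
    ``step_log2`` is the per-interval expression step for ``u``/``d``
    characters; ``line_sd`` the total per-line offset SD on the log2
    scale (split between module-shared genetic value and transcript
    noise according to ``h2_module``); ``latent_sd`` scales the latent
    batch factor; ``resid_sd`` adds sample-level log-normal noise beyond
    the NB sampling noise.
    """
    if depth_range[0] <= 0 or depth_range[1] < depth_range[0]:
        raise ValueError("depth_range must be a positive interval")
    rng = np.random.default_rng(seed)
    md = sample_table(design, rng)
    n_s = len(md)
    tx = truth.transcript_ids
    n_t = len(tx)

    profiles = np.vstack([
        _pattern_profile(code, step_log2, design.n_times)
        for code in truth.patterns])
    time_idx = np.searchsorted(np.asarray(design.time_points),
                               md["daa"].to_numpy())
    line_idx = pd.Categorical(md["line"], categories=design.lines).codes

    base = rng.uniform(*base_log2_range, size=n_t)

    # per-line offsets: module-shared genetic value + transcript noise
    module_keys = list(zip(truth.modules["tcoe_id"], truth.modules["gcoe_id"]))
    offsets = np.empty((n_t, design.n_lines))
    for i, key in enumerate(module_keys):
        h2 = truth.h2_module[key]
        u = truth.line_values[key]  # variance ~ h2 (unit total)
        eps = rng.standard_normal(design.n_lines) * np.sqrt(max(1.0 - h2, 0.0))
        offsets[i] = line_sd * (u + eps)

    factor = rng.standard_normal(n_s)
    log2mu = (base[:, None]
              + profiles[:, time_idx]
              + offsets[:, line_idx]
              + latent_sd * np.outer(truth.latent_loadings.to_numpy(), factor))
    if resid_sd > 0:
        log2mu = log2mu + rng.standard_normal((n_t, n_s)) * resid_sd

    depth = np.exp(rng.uniform(np.log(depth_range[0]),
                               np.log(depth_range[1]), n_s))
    mean = (2.0 ** np.clip(log2mu, -20, 25)) * depth[None, :]

    disp = truth.dispersion.to_numpy()[:, None]
    # gamma-Poisson mixture == NB with mean `mean`, dispersion `disp`
    shape = 1.0 / np.maximum(disp, 1e-12)
    lam = np.where(disp > 1e-8,
                   rng.gamma(np.broadcast_to(shape, mean.shape),
                             disp * mean),
                   mean)
    counts = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=tx, columns=md.index), md)
    return cm, cm.metadata


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

def simulate_metabolites(truth: SimulationTruth, pc1_truth: dict,
                         design: StudyDesign,
                         noise_variances: tuple = (0.25, 0.25),
                         loc_var: float = 0.1, rep_var: float = 0.1,
                         seed: int = 0) -> pd.DataFrame:
    """Mature-seed metabolite values, one per line x location x replicate.

    ``value = beta * PC1_line + Location + Location:Line +
    Replication(Location) + residual``.  ``noise_variances`` is the pair
    (location-by-line variance, residual variance).  Metabolites listed
    in ``truth.metabolite_links`` are driven by the per-line PC1 signal
    of their module (``pc1_truth[(tcoe_id, gcoe_id)]``); unlinked
    metabolites (beta 0 rows) are pure design noise.

    Returns a long-format table with columns
    ``metabolite, line, location, replicate, value``.
    """
    v_ll, v_e = noise_variances
    if min(v_ll, v_e, loc_var, rep_var) < 0:
        raise ValueError("variances must be non-negative")
    links = truth.metabolite_links
    for key in zip(links["tcoe_id"], links["gcoe_id"]):
        if links.loc[(links["tcoe_id"] == key[0])
                     & (links["gcoe_id"] == key[1]), "beta"].abs().sum() > 0 \
                and key not in pc1_truth:
            raise ValueError(f"module {key} linked but absent from pc1_truth")
    rng = np.random.default_rng(seed)

    lines = design.lines
    locs = [f"S{j}" for j in range(1, design.n_locations + 1)]
    reps = list(range(1, design.n_reps + 1))
    plots = pd.DataFrame(
        [(li, lo, re) for li in lines for lo in locs for re in reps],
        columns=["line", "location", "replicate"])
    line_idx = pd.Categorical(plots["line"], categories=lines).codes
    loc_idx = pd.Categorical(plots["location"], categories=locs).codes
    rep_of_loc = loc_idx * design.n_reps + (plots["replicate"].to_numpy() - 1)

    out = []
    for row in links.itertuples():
        key = (row.tcoe_id, row.gcoe_id)
        signal = np.zeros(len(lines))
        if row.beta != 0:
            signal = row.beta * np.asarray(pc1_truth[key], float)
        b_loc = rng.normal(0, np.sqrt(loc_var), design.n_locations)
        b_rep = rng.normal(0, np.sqrt(rep_var),
                           design.n_locations * design.n_reps)
        b_ll = rng.normal(0, np.sqrt(v_ll),
                          (design.n_locations, len(lines)))
        e = rng.normal(0, np.sqrt(v_e), len(plots))
        value = (signal[line_idx] + b_loc[loc_idx] + b_rep[rep_of_loc]
                 + b_ll[loc_idx, line_idx] + e)
        block = plots.copy()
        block.insert(0, "metabolite", row.metabolite)
        block["value"] = value
        out.append(block)
    return pd.concat(out, ignore_index=True)
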