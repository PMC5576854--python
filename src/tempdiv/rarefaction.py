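"""Individual-based rarefaction and per-plot / per-sample diversity tables.

Temporal gamma diversity is computed on plot totals pooled across a
season's temporal samples; temporal alpha diversity on each individual
sample. Both rarefy to a common number of individuals (repeated random
subsampling without replacement) so that richness and Pielou evenness are
compared at equal effort, and both carry the variance-stabilising
transforms used downstream: logit for proportions (evenness, generalist
share) and cube root for abundance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "RarefactionConfig",
    "RarefiedStats",
    "shannon",
    "pielou",
    "expected_richness_analytic",
    "rarefy_stats",
    "generalist_proportion",
    "logit_adj",
    "gamma_table",
    "alpha_table",
]


@dataclass
class RarefactionConfig:
    """Settings for the rarefied diversity tables.

    alpha_depth
        Individuals drawn per temporal sample (default 20); samples with
        fewer individuals are flagged excluded from rarefied metrics.
    gamma_depth
        Individuals drawn per pooled plot; ``"auto"`` uses the lowest
        pooled plot total in the year analysed.
    iterations
        Rarefaction draws averaged per unit (default 1000).
    seed
        Master seed; every unit gets its own deterministic substream
        derived from (seed, unit key), so results do not depend on row
        order or parallel scheduling.
    """

    alpha_depth: int = 20
    gamma_depth: int | str = "auto"
    iterations: int = 1000
    seed: int = 0


@dataclass
class RarefiedStats:
    mean_richness: float
    mean_evenness: float  # nan when every draw had S=1
    iterations_used: int
    draws_skipped_evenness: int
    richness_sd: float = 0.0  # across-draw sd; /sqrt(iterations) gives the MC SE

    @property
    def richness_se(self) -> float:
        return self.richness_sd / np.sqrt(self.iterations_used)


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero count vector")
    return c


def shannon(counts) -> float:
    """Shannon entropy H' = -sum p_i ln p_i (natural log, nonzero taxa)."""
    c = _as_counts(counts).astype(float)
    p = c[c > 0]
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def pielou(counts) -> float:
    """Pielou's evenness J = H' / ln S; ``nan`` when only one taxon (S=1)."""
    c = _as_counts(counts)
    s = int((c > 0).sum())
    if s == 1:
        return float("nan")
    return shannon(c) / np.log(s)


def expected_richness_analytic(counts, depth: int) -> float:
    """Expected richness of a random subsample of `depth` individuals.

    Hypergeometric (Hurlbert) expectation
    ``sum_i [1 - C(N - N_i, d) / C(N, d)]`` — the exact mean of
    individual-based rarefaction, used as the independent oracle for the
    Monte-Carlo routine. Computed with log-gamma for numerical safety.
    """
    c = _as_counts(counts)
    n = int(c.sum())
    if depth > n:
        raise ValueError(f"depth {depth} exceeds total individuals {n}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    ni = c[c > 0].astype(float)

    def _logchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        log_p_absent = _logchoose(n - ni, depth) - _logchoose(n, depth)
    # species with N_i > N - depth are always present in the subsample
    p_absent = np.where(n - ni >= depth, np.exp(log_p_absent), 0.0)
    return float((1.0 - p_absent).sum())


def _draw_matrix(rng: np.random.Generator, counts: np.ndarray, depth: int,
                 iterations: int) -> np.ndarray:
    """(iterations, taxa) matrix of multivariate-hypergeometric subsamples.

    Zero-count taxa are dropped before drawing (they cannot appear in a
    subsample and only slow the sampler); the "count" algorithm scales
    with iterations x depth, which beats the per-taxon marginal sampler
    at every depth used here.
    """
    nz = counts > 0
    draws = rng.multivariate_hypergeometric(counts[nz], depth, size=iterations,
                                            method="count")
    out = np.zeros((iterations, len(counts)), dtype=draws.dtype)
    out[:, nz] = draws
    return out


def _richness_evenness(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-draw richness and Pielou J (nan where S=1) from a draw matrix."""
    pos = draws > 0
    s = pos.sum(axis=1)
    totals = draws.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = draws / totals
        h = -np.where(pos, p * np.log(np.where(pos, p, 1.0)), 0.0).sum(axis=1)
        j = np.where(s >= 2, h / np.log(np.maximum(s, 2)), np.nan)
    return s.astype(float), j, int((s < 2).sum())


def rarefy_stats(counts, depth: int, iterations: int = 1000,
                 seed: int | np.random.Generator = 0) -> RarefiedStats:
    """Monte-Carlo rarefaction of one count vector.

    Each iteration draws `depth` individuals without replacement from the
    pool of individuals implied by `counts`; the mean richness and mean
    Pielou J across iterations are returned. Draws in which a single
    species is drawn carry no defined evenness; they are skipped from the
    J average and counted in ``draws_skipped_evenness``.

    When ``depth`` equals the total the draw is exhaustive and a single
    deterministic iteration is used.
    """
    c = _as_counts(counts).astype(np.int64)
    n = int(c.sum())
    if depth > n:
        raise ValueError(f"depth {depth} exceeds total individuals {n}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = c[c > 0]  # zero taxa cannot enter a subsample
    if depth == n:
        draws = c[None, :]
        iterations = 1
    else:
        draws = _draw_matrix(rng, c, depth, iterations)
    s, j, skipped = _richness_evenness(draws)
    mean_j = float(np.nanmean(j)) if skipped < len(j) else float("nan")
    return RarefiedStats(
        mean_richness=float(s.mean()),
        mean_evenness=mean_j,
        iterations_used=iterations,
        draws_skipped_evenness=skipped,
        richness_sd=float(s.std(ddof=1)) if iterations > 1 else 0.0,
    )


def generalist_proportion(counts, diets) -> float:
    """Share of individuals belonging to pollen-generalist species.

    ``diets`` is a sequence aligned with `counts` giving each taxon's diet
    class. Only generalists and specialists enter the ratio; parasitic
    and unknown-diet taxa are excluded from both numerator and
    denominator (diet breadth is defined for pollen-collecting species
    only). Returns ``nan`` when no generalist or specialist individuals
    are present.
    """
    c = np.asarray(counts, dtype=float)
    d = np.asarray(diets, dtype=object)
    if c.shape != d.shape:
        raise ValueError("counts and diets must be aligned")
    gen = c[d == "generalist"].sum()
    spec = c[d == "specialist"].sum()
    if gen + spec == 0:
        return float("nan")
    return float(gen / (gen + spec))


def logit_adj(p: float, n_individuals: int) -> float:
    """Logit transform with boundary shrinkage.

    Interior proportions map through the plain logit ``ln(p / (1-p))``.
    Exactly 0 or 1 are first shrunk toward 1/2 by
    ``p' = (p (n-1) + 0.5) / n`` with n the number of individuals behind
    the proportion, keeping boundary plots on the transformed scale
    without perturbing interior values.
    """
    if np.isnan(p):
        return float("nan")
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion outside [0, 1]")
    if p in (0.0, 1.0):
        if n_individuals < 1:
            raise ValueError("n_individuals must be >= 1 for boundary shrinkage")
        p = (p * (n_individuals - 1) + 0.5) / n_individuals
    return float(np.log(p / (1.0 - p)))


def _unit_rng(seed: int, unit_key) -> np.random.Generator:
    """Deterministic per-unit substream from (seed, unit key)."""
    tag = zlib.crc32(repr(unit_key).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _diet_lookup(taxa, traits: pd.DataFrame | None, taxon_level: str) -> np.ndarray | None:
    """Diet class per matrix column; None when diets are unavailable.

    Diet breadth is a species-level trait; genus-level matrices do not
    carry a well-defined generalist share and get no diet lookup.
    """
    if traits is None or taxon_level != "species":
        return None
    diets = traits.set_index("species_id")["diet"]
    missing = [t for t in taxa if t not in diets.index]
    if missing:
        raise ValueError(f"taxa missing from traits table: {missing[:5]}")
    return diets.loc[list(taxa)].to_numpy(dtype=object)


def gamma_table(matrix, traits=None, config: RarefactionConfig | None = None) -> pd.DataFrame:
    """Per-plot temporal gamma diversity table from a pooled plot matrix.

    The rarefaction depth defaults to the lowest pooled plot total in the
    matrix ("auto"), so every plot is subsampled to the poorest plot's
    abundance. Output rows carry observed and rarefied richness, logit
    rarefied evenness, logit generalist proportion, raw abundance and the
    cube-root of mean per-sample abundance (total divided by the number
    of temporal samples recorded in the matrix metadata).

    Parameters
    ----------
    matrix : AbundanceMatrix
        Pooled plot-by-taxon matrix (see
        :func:`tempdiv.data_model.pool_by_plot`); its ``meta`` must carry
        ``treatment`` and ``n_samples``.
    """
    config = config or RarefactionConfig()
    counts = matrix.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    depth = int(totals.min()) if config.gamma_depth == "auto" else int(config.gamma_depth)
    diets = _diet_lookup(matrix.taxa, traits, matrix.taxon_level)

    rows = []
    for i, plot in enumerate(matrix.counts.index):
        c = counts[i]
        meta = matrix.meta.iloc[i]
        row = {
            "plot_id": plot,
            "treatment": meta["treatment"],
            "n_samples": int(meta["n_samples"]),
            "raw_abundance": int(totals[i]),
            "observed_richness": int((c > 0).sum()),
            "depth": depth,
            "exclusion_reason": "",
        }
        mean_ab = totals[i] / meta["n_samples"]
        row["abundance_transformed"] = float(np.cbrt(mean_ab))
        if totals[i] < depth:
            row["exclusion_reason"] = f"total {totals[i]} below depth {depth}"
            row.update(rarefied_richness=np.nan, evenness_logit=np.nan)
        else:
            st = rarefy_stats(c, depth, config.iterations,
                              _unit_rng(config.seed, ("gamma", plot)))
            row["rarefied_richness"] = st.mean_richness
            row["evenness_logit"] = logit_adj(st.mean_evenness, depth) \
                if np.isfinite(st.mean_evenness) else np.nan
        if diets is not None:
            p = generalist_proportion(c, diets)
            denom = int(c[(diets == "generalist") | (diets == "specialist")].sum())
            row["generalist_prop"] = p
            row["generalist_prop_logit"] = logit_adj(p, denom) if denom else np.nan
        else:
            row["generalist_prop"] = np.nan
            row["generalist_prop_logit"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def alpha_table(matrix, traits=None, config: RarefactionConfig | None = None) -> pd.DataFrame:
    """Per-sample temporal alpha diversity table from a sample matrix.

    Samples with fewer individuals than ``alpha_depth`` are flagged with
    an ``exclusion_reason`` and carry no rarefied metrics, but keep their
    abundance columns: abundance is analysed without rarefaction, so no
    sample is dropped from it.
    """
    config = config or RarefactionConfig()
    depth = int(config.alpha_depth)
    counts = matrix.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    diets = _diet_lookup(matrix.taxa, traits, matrix.taxon_level)

    rows = []
    for i, key in enumerate(matrix.counts.index):
        plot, year, jd = key
        c = counts[i]
        row = {
            "plot_id": plot,
            "year": int(year),
            "julian_date": int(jd),
            "treatment": matrix.meta.iloc[i]["treatment"],
            "raw_abundance": int(totals[i]),
            "observed_richness": int((c > 0).sum()),
            "depth": depth,
            "abundance_transformed": float(np.cbrt(totals[i])),
            "exclusion_reason": "",
        }
        if totals[i] < depth:
            row["exclusion_reason"] = f"total {totals[i]} below depth {depth}"
            row.update(rarefied_richness=np.nan, evenness_logit=np.nan)
        else:
            st = rarefy_stats(c, depth, config.iterations,
                              _unit_rng(config.seed, ("alpha", plot, int(year), int(jd))))
            row["rarefied_richness"] = st.mean_richness
            row["evenness_logit"] = logit_adj(st.mean_evenness, depth) \
                if np.isfinite(st.mean_evenness) else np.nan
        if diets is not None:
            p = generalist_proportion(c, diets)
            denom = int(c[(diets == "generalist") | (diets == "specialist")].sum())
            row["generalist_prop"] = p
            row["generalist_prop_logit"] = logit_adj(p, denom) if denom else np.nan
        else:
            row["generalist_prop"] = np.nan
            row["generalist_prop_logit"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
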