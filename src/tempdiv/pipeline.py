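"""One-call orchestration: filter -> matrices -> gamma / alpha / beta -> tests.

`run_analysis` runs a full single-year analysis on validated survey and
trait tables and returns a report bundle (plain dict of DataFrames and
metadata) that `write_report` serialises as tidy CSV + JSON. Years are
analysed independently; `run_analysis` handles exactly one year.

`power_study` repeats simulate -> analyse on a preset and tallies
rejection rates, which is how the package quantifies the sensitivity of
the whole pipeline to injected disturbance effects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_model as dm
from . import ordination as od
from . import rarefaction as rf
from .inference import fit_lmm, select_degree, welch_t
from .synthetic import (
    SimConfig,
    estimate_richness_deficit,
    simulate_matrix,
    simulate_survey,
)

logger = logging.getLogger(__name__)

GAMMA_RESPONSES = [
    "rarefied_richness",
    "evenness_logit",
    "generalist_prop_logit",
    "abundance_transformed",
]
ALPHA_RESPONSES = GAMMA_RESPONSES


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    year: int | None = None
    keep_methods: tuple[str, ...] = ("bowl",)
    drop_nonnative: bool = True
    drop_genus_only: bool = True
    taxon_level: str = "species"
    alpha_depth: int = 20
    gamma_depth: int | str = "auto"
    iterations: int = 1000
    k: int = 2
    n_restarts: int = 20
    max_iter: int = 300
    tol: float = 1e-7
    standardize: str = "none"
    engine: str = "nmds"
    tests: str = "sequential"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    class _Stage:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"analysis stage {name!r} failed: {exc}") from exc

    return _Stage()


def _welch_table(table: pd.DataFrame, responses: list[str],
                 value_filter=None) -> pd.DataFrame:
    rows = []
    for resp in responses:
        sub = table if value_filter is None else table[value_filter(table)]
        x = sub.loc[sub["treatment"] == "reserve", resp]
        y = sub.loc[sub["treatment"] == "fragment", resp]
        try:
            w = welch_t(x, y)
        except ValueError as err:
            rows.append({"response": resp, "error": str(err)})
            continue
        rows.append({
            "response": resp, "t": w.t, "df": w.df, "p": w.p_two_sided,
            "mean_reserve": w.mean_x, "mean_fragment": w.mean_y,
            "n_reserve": w.n_x, "n_fragment": w.n_y,
        })
    return pd.DataFrame(rows)


def analyze_matrix(matrix: dm.AbundanceMatrix, traits: pd.DataFrame | None,
                   config: RunConfig) -> dict:
    """Run the gamma / alpha / beta analyses on a filtered sample matrix."""
    rar_cfg = rf.RarefactionConfig(alpha_depth=config.alpha_depth,
                                   gamma_depth=config.gamma_depth,
                                   iterations=config.iterations,
                                   seed=config.seed)

    with _stage("gamma"):
        pooled = dm.pool_by_plot(matrix)
        treat_counts = pooled.meta["treatment"].value_counts()
        if treat_counts.reindex(["reserve", "fragment"]).fillna(0).min() < 2:
            raise ValueError(
                f"need >= 2 plots per treatment, got {treat_counts.to_dict()}"
            )
        gamma = rf.gamma_table(pooled, traits, rar_cfg)
        gamma_welch = _welch_table(gamma, GAMMA_RESPONSES)

    with _stage("alpha"):
        alpha = rf.alpha_table(matrix, traits, rar_cfg)
        lmm_rows, lmm_selected = [], {}
        for resp in ALPHA_RESPONSES:
            if alpha[resp].notna().sum() < 10:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits = {d: fit_lmm(alpha, resp, d, tests=config.tests)
                            for d in (1, 2, 3)}
                chosen = select_degree(fits)
            except ValueError as err:
                logger.warning("LMM for %s skipped: %s", resp, err)
                continue
            lmm_selected[resp] = chosen
            for d, f in fits.items():
                tab = f.anova.assign(response=resp, degree=d, aic=f.aic,
                                     selected=(d == chosen.degree))
                lmm_rows.append(tab)
        lmm = (pd.concat(lmm_rows, ignore_index=True)
               if lmm_rows else pd.DataFrame())

    with _stage("beta"):
        dmat = od.dissimilarity_matrix(matrix, standardize=config.standardize)
        if config.engine == "pcoa":
            coords = od.pcoa(dmat.to_numpy(), config.k)
            ordination = None
            coord_arr = coords
            stress = np.nan
        else:
            ordination = od.nmds(dmat, k=config.k, n_restarts=config.n_restarts,
                                 max_iter=config.max_iter, tol=config.tol,
                                 seed=config.seed)
            coord_arr = ordination.coords_array()
            stress = ordination.stress
        plot_of_sample = matrix.counts.index.get_level_values("plot_id")
        disp = od.dispersion_scores(coord_arr, plot_of_sample)
        scores = disp.scores.merge(
            pooled.meta.reset_index()[["plot_id", "treatment"]], on="plot_id"
        )
        disp_welch = _welch_table(scores, ["dispersion"])

    return {
        "gamma": gamma,
        "gamma_welch": gamma_welch,
        "alpha": alpha,
        "lmm": lmm,
        "lmm_selected": lmm_selected,
        "dispersion": scores,
        "dispersion_welch": disp_welch,
        "nmds_stress": float(stress),
        "ordination": ordination,
        "config": config.to_dict(),
    }


def run_analysis(records: pd.DataFrame, traits: pd.DataFrame,
                 config: RunConfig) -> dict:
    """Full single-year pipeline from validated long-format records.

    Applies the filtering rules, restricts to the configured year (a
    single-year table needs no selector), pivots, and runs
    :func:`analyze_matrix`. Every exclusion and the master seed end up
    in the returned bundle.
    """
    with _stage("filter"):
        years = sorted(records["year"].unique())
        if config.year is None:
            if len(years) > 1:
                raise ValueError(f"multiple years present {years}; set config.year")
            year = years[0]
        else:
            year = config.year
            if year not in years:
                raise ValueError(f"year {year} absent from records (have {years})")
        records = records[records["year"] == year]
        filtered, report = dm.filter_records(
            records, keep_methods=set(config.keep_methods),
            drop_nonnative=config.drop_nonnative,
            drop_genus_only=config.drop_genus_only,
            traits=traits,
        )
        matrix = dm.to_matrix(filtered, taxon_level=config.taxon_level,
                              traits=traits)
    bundle = analyze_matrix(matrix, traits, config)
    bundle["year"] = int(year)
    bundle["filter_report"] = {"rows_in": report.rows_in,
                               "rows_out": report.rows_out,
                               "removed": report.removed}
    return bundle


def write_report(bundle: dict, out_dir) -> None:
    """Serialise a report bundle to tidy CSVs plus a JSON run log.

    On failure the partially written directory content is removed, so an
    output directory never holds a half-report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for key in ("gamma", "gamma_welch", "alpha", "lmm", "dispersion",
                    "dispersion_welch"):
            df = bundle.get(key)
            if isinstance(df, pd.DataFrame) and len(df):
                path = out / f"{key}.csv"
                df.to_csv(path, index=False)
                written.append(path)
        log = {
            "year": bundle.get("year"),
            "config": bundle.get("config"),
            "filter_report": bundle.get("filter_report"),
            "nmds_stress": bundle.get("nmds_stress"),
            "selected_degrees": {r: f.degree
                                 for r, f in bundle.get("lmm_selected", {}).items()},
            "alpha_exclusions": bundle["alpha"].loc[
                bundle["alpha"]["exclusion_reason"] != "",
                ["plot_id", "julian_date", "exclusion_reason"],
            ].to_dict("records") if "alpha" in bundle else [],
        }
        path = out / "run_log.json"
        path.write_text(json.dumps(log, indent=2, default=str))
        written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_simulation(sim_config: SimConfig, out_dir) -> dict:
    """Simulate a survey and write survey.csv, traits.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_survey(sim_config)
    dm.write_survey(sim.records, out / "survey.csv")
    dm.write_traits(sim.traits, out / "traits.csv")
    (out / "truth.json").write_text(json.dumps(sim.truth, indent=2))
    return {"records": len(sim.records), "out": str(out)}


def power_study(sim_config: SimConfig, reps: int, seed: int = 0,
                run_config: RunConfig | None = None, alpha_level: float = 0.05,
                do_beta: bool = True, do_lmm: bool = True) -> dict:
    """Rejection rates of the pipeline's tests over repeated simulations.

    Each repetition draws a fresh survey from `sim_config` (reseeded
    from `seed`), runs the matrix-level pipeline, and records the
    two-sided p-values of the four gamma Welch tests, the dispersion
    Welch test and the mixed-model treatment term for rarefied richness.
    Returns per-test rejection rates plus the mean relative
    reserve-to-fragment differences, which ground-truth-recovery checks
    compare against the injected effects.

    Problem sizes: repeated-simulation studies default to lighter
    rarefaction iteration counts and ordination restarts than a single
    analysis run (see the ``run_config`` default below); calibration and
    power are insensitive to these since every plot and treatment shares
    the same settings.
    """
    rc = run_config or RunConfig(iterations=200, n_restarts=1, max_iter=100,
                                 tol=1e-4)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(reps).astype(np.int64) % (2**31 - 1)

    pvals: dict[str, list] = {}
    diffs: dict[str, list] = {}
    degrees: list[int] = []
    for r in range(reps):
        cfg = dataclasses.replace(sim_config, seed=int(child_seeds[r]))
        matrix, traits, _truth = simulate_matrix(cfg)
        rep_rc = dataclasses.replace(rc, seed=int(child_seeds[r]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rar_cfg = rf.RarefactionConfig(alpha_depth=rep_rc.alpha_depth,
                                           gamma_depth=rep_rc.gamma_depth,
                                           iterations=rep_rc.iterations,
                                           seed=rep_rc.seed)
            pooled = dm.pool_by_plot(matrix)
            gamma = rf.gamma_table(pooled, traits, rar_cfg)
            gw = _welch_table(gamma, GAMMA_RESPONSES)
            for _, row in gw.iterrows():
                pvals.setdefault(row["response"], []).append(row.get("p", np.nan))
                diffs.setdefault(row["response"], []).append(
                    row.get("mean_reserve", np.nan) - row.get("mean_fragment", np.nan)
                )
            res = gamma.loc[gamma["treatment"] == "reserve", "observed_richness"]
            frag = gamma.loc[gamma["treatment"] == "fragment", "observed_richness"]
            diffs.setdefault("observed_richness_ratio", []).append(
                frag.mean() / res.mean()
            )
            # pooled within treatment: deeper detection for deficit recovery
            counts = matrix.counts.to_numpy()
            treat = pooled.meta["treatment"]
            res_plots = set(treat.index[treat == "reserve"])
            plot_ids = matrix.counts.index.get_level_values("plot_id")
            is_res = np.asarray([p in res_plots for p in plot_ids])
            s_res = int((counts[is_res].sum(axis=0) > 0).sum())
            s_frag = int((counts[~is_res].sum(axis=0) > 0).sum())
            diffs.setdefault("pooled_richness_ratio", []).append(s_frag / s_res)
            diffs.setdefault("deficit_estimate", []).append(
                estimate_richness_deficit(matrix))

            if do_lmm:
                alpha_tab = rf.alpha_table(matrix, traits, rar_cfg)
                try:
                    fits = {d: fit_lmm(alpha_tab, "rarefied_richness", d)
                            for d in (1, 2, 3)}
                    chosen = select_degree(fits)
                    degrees.append(chosen.degree)
                    tr = chosen.anova.set_index("term").loc["treatment", "p"]
                    pvals.setdefault("lmm_treatment_richness", []).append(float(tr))
                    alpha_diff = (
                        alpha_tab.loc[alpha_tab["treatment"] == "reserve",
                                      "rarefied_richness"].mean()
                        - alpha_tab.loc[alpha_tab["treatment"] == "fragment",
                                        "rarefied_richness"].mean()
                    )
                    diffs.setdefault("alpha_richness", []).append(float(alpha_diff))
                except ValueError:
                    pvals.setdefault("lmm_treatment_richness", []).append(np.nan)

            if do_beta:
                dmat = od.dissimilarity_matrix(matrix)
                ordn = od.nmds(dmat, k=rep_rc.k, n_restarts=rep_rc.n_restarts,
                               max_iter=rep_rc.max_iter, tol=rep_rc.tol,
                               seed=rep_rc.seed)
                plot_of_sample = matrix.counts.index.get_level_values("plot_id")
                disp = od.dispersion_scores(ordn.coords_array(), plot_of_sample)
                scores = disp.scores.merge(
                    pooled.meta.reset_index()[["plot_id", "treatment"]],
                    on="plot_id")
                dw = _welch_table(scores, ["dispersion"])
                pvals.setdefault("dispersion", []).append(
                    float(dw["p"].iloc[0]) if "p" in dw else np.nan)
                diffs.setdefault("dispersion", []).append(
                    float(dw["mean_reserve"].iloc[0] - dw["mean_fragment"].iloc[0])
                    if "mean_reserve" in dw else np.nan)

    out = {
        "reps": reps,
        "alpha_level": alpha_level,
        "rejection_rates": {
            k: float(np.nanmean(np.asarray(v) < alpha_level))
            for k, v in pvals.items()
        },
        "mean_differences": {k: float(np.nanmean(v)) for k, v in diffs.items()},
        "pvalues": {k: [float(x) for x in v] for k, v in pvals.items()},
        "differences": {k: [float(x) for x in v] for k, v in diffs.items()},
        "selected_degrees": degrees,
    }
    return out
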