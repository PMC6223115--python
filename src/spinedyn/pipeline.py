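"""End-to-end analysis pipeline: simulate -> estimate -> fit -> predict -> report.

Two entry points:

* :func:`run_replication_preset` evaluates the model's headline predictions
  directly from the published coefficient laws (no data): stationary volume
  distributions and their means, per-session elimination rates for both the
  discrete-observation and first-passage functionals, the drift zero
  crossing, the algebraic intercepts of the anchored fits, and the
  neocortex/hippocampus linear-slope attenuation ratio.

* :func:`run_full_pipeline` exercises the whole measurement chain on
  synthetic cohorts: generate trajectories, extract transitions, bin
  moments, decompose fast/slow, fit the coefficient laws, recompute the
  model predictions from the *fitted* laws, and run the group comparisons
  (anchored-slope interaction, Mann-Whitney U on per-dendrite elimination
  fractions, Kolmogorov-Smirnov on volume samples).
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import estimation, fp
from .model import DriftDiffusionSpec, KO_SPEC, WT_SPEC
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "PipelineError",
    "ANCHOR_ABSCISSA",
    "anchored_intercept",
    "run_replication_preset",
    "run_full_pipeline",
    "FAST_COHORT_SCALE",
]

#: printed abscissa of the anchor point: 0.015**(2/3) rounded to 0.06
ANCHOR_ABSCISSA = 0.06

#: linear-in-V slope of the adult-neocortex WT fit and the corresponding
#: young-hippocampus slope from the earlier literature; their ratio
#: quantifies how little the fluctuations are attenuated relative to a
#: purely multiplicative model.
NEOCORTEX_LINEAR_SLOPE = 0.21
HIPPOCAMPUS_LINEAR_SLOPE = 0.28

#: scale of the 10-min fast-imaging cohorts (spines / dendrites / animals)
FAST_COHORT_SCALE = {
    "n_spines": {"WT": 475, "KO": 1433},
    "n_dendrites": {"WT": 2, "KO": 4},
    "n_animals": {"WT": 2, "KO": 3},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def anchored_intercept(slope: float, anchor_x: float = ANCHOR_ABSCISSA,
                       anchor_sigma: float = estimation.ANCHOR_SIGMA) -> float:
    """Intercept of ``slope*(x - anchor_x) + anchor_sigma`` expanded in x."""
    return anchor_sigma - slope * anchor_x


def run_replication_preset(
    out_dir: str | Path | None = None,
    n_grid: int = 4000,
    n_time: int = 2000,
    make_figures: bool = False,
) -> pd.DataFrame:
    """Model predictions from the published coefficient laws.

    Returns a tidy table of named quantities; writes ``preset_table.csv``
    (and figures) under ``out_dir`` when given.  Deterministic: no random
    numbers are involved.
    """
    specs = {"WT": WT_SPEC, "KO": KO_SPEC}
    rows = []
    densities = {}
    for g, spec in specs.items():
        dens = fp.stationary_density(spec, n_grid)
        densities[g] = dens
        rows.append((f"{g} stationary mean volume (um3)", fp.stationary_mean(dens)))
    for g, spec in specs.items():
        rows.append((
            f"{g} elimination per 2 d (model, %)",
            fp.session_elimination_rate(spec),
        ))
    for g, spec in specs.items():
        rows.append((
            f"{g} first-passage elimination per 2 d (%)",
            fp.elimination_rate(spec, n_grid=n_grid, n_time=n_time),
        ))
    rows.append(("drift zero crossing (um3)", WT_SPEC.drift_zero_crossing()))
    rows.append(("WT anchored intercept", anchored_intercept(WT_SPEC.slow_slope)))
    rows.append(("KO anchored intercept", anchored_intercept(KO_SPEC.slow_slope)))
    rows.append((
        "linear-slope attenuation ratio (neocortex/hippocampus)",
        NEOCORTEX_LINEAR_SLOPE / HIPPOCAMPUS_LINEAR_SLOPE,
    ))
    table = pd.DataFrame(rows, columns=["quantity", "value"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "preset_table.csv", index=False)
        for g, dens in densities.items():
            pd.DataFrame({"volume_um3": dens.grid, "density": dens.density}).to_csv(
                out / f"stationary_density_{g}.csv", index=False
            )
        if make_figures:
            _preset_figures(densities, table, out)
    return table


def _preset_figures(densities, table, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    v = np.linspace(0.01, 1.0, 400)
    for g, spec in (("WT", WT_SPEC), ("KO", KO_SPEC)):
        axes[0].plot(v ** (2 / 3), spec.sigma_slow(v), label=f"{g} slow SD")
    axes[0].plot(v ** (2 / 3), WT_SPEC.sigma_fast(v), "k:", label="fast SD")
    axes[0].plot(v ** (2 / 3), WT_SPEC.mu(v), "r--", label="drift")
    axes[0].set_xlabel(r"$V^{2/3}$ ($\mu m^2$)")
    axes[0].set_ylabel(r"$\mu m^3$ per 2 d")
    axes[0].legend(fontsize=7)
    for g, dens in densities.items():
        axes[1].plot(dens.grid, dens.density, label=g)
    axes[1].set_xlabel(r"V ($\mu m^3$)")
    axes[1].set_ylabel(r"f(V) (1/$\mu m^3$)")
    axes[1].set_xlim(0, 0.6)
    axes[1].legend()
    elim = table[table["quantity"].str.contains("elimination per 2 d .model")]
    axes[2].bar(["WT", "KO"], elim["value"].to_numpy(), hatch="//", fill=False)
    axes[2].set_ylabel("predicted elimination (% per 2 d)")
    fig.tight_layout()
    fig.savefig(out / "replication_preset.png", dpi=150)
    plt.close(fig)


def _stage(tag: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{tag}] {exc}") from exc
        return wrapped
    return deco


def run_full_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    bin_size: int = estimation.DEFAULT_BIN_SIZE,
    fast_bin_size: int = 30,
    predict_grid: int = 2000,
    predict_time: int = 500,
) -> dict:
    """Simulate cohorts, re-estimate the model, predict, and compare groups.

    Returns the run manifest (also written as ``manifest.json``); all
    intermediate tables are persisted as CSV under ``out_dir``.  Re-running
    with the same config reproduces every artifact bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = sorted(config.specs)

    table = _stage("simulate")(generate_cohort)(config)
    table.to_csv(out / "trajectories.csv", index=False)
    fast_kwargs = {}
    if all(g in FAST_COHORT_SCALE["n_spines"] for g in groups):
        fast_kwargs = {
            k: {g: v[g] for g in groups} for k, v in FAST_COHORT_SCALE.items()
        }
    fast_cfg = replace(config, mode="fast", seed=config.seed + 1, **fast_kwargs)
    fast_table = _stage("simulate")(generate_cohort)(fast_cfg)
    fast_table.to_csv(out / "fast_trajectories.csv", index=False)

    @_stage("estimate")
    def _estimate():
        per_group = {}
        pooled_trans = []
        for g in groups:
            trans, _ = estimation.pair_transitions(table[table["group"] == g])
            if len(trans) == 0:
                raise ValueError(f"no transitions for group {g} (too few sessions?)")
            per_group[g] = estimation.bin_and_moment(trans, bin_size)
            pooled_trans.append(trans)
        fast_trans, _ = estimation.pair_transitions(fast_table)
        fast_moments = estimation.bin_and_moment(fast_trans, fast_bin_size)
        pooled = estimation.bin_and_moment(
            pd.concat(pooled_trans, ignore_index=True), bin_size
        )
        return per_group, pooled, fast_moments

    moments, pooled_moments, fast_moments = _estimate()
    for g, m in moments.items():
        m.table.to_csv(out / f"moments_2d_{g}.csv", index=False)
    fast_moments.table.to_csv(out / "moments_fast.csv", index=False)

    @_stage("fit")
    def _fit():
        fast = estimation.fit_fast(fast_moments)
        drift = estimation.fit_drift(pooled_moments)
        slow = {}
        fitted = {}
        for g in groups:
            slow[g] = estimation.decompose_slow(moments[g], fast)
            slope, ci = estimation.fit_anchored_slope(slow[g])
            fitted[g] = {
                "spec": config.specs[g].replace(
                    slow_slope=slope,
                    slow_intercept=anchored_intercept(
                        slope, anchor_x=estimation.ANCHOR_V ** (2 / 3)
                    ),
                    drift_slope=drift[0], drift_intercept=drift[1],
                    fast_slope=fast[0], fast_intercept=fast[1],
                ),
                "slow_slope_ci": ci,
            }
        return fast, drift, slow, fitted

    fast_coeffs, drift_coeffs, slow_moments, fitted = _fit()
    for g in groups:
        fitted[g]["spec"].to_json(out / f"fitted_spec_{g}.json")

    @_stage("predict")
    def _predict():
        pred = {}
        for g in groups:
            spec = fitted[g]["spec"]
            dens = fp.stationary_density(spec, predict_grid)
            pred[g] = {
                "stationary_mean_um3": fp.stationary_mean(dens),
                "session_elimination_pct": fp.session_elimination_rate(spec),
                "first_passage_elimination_pct": fp.elimination_rate(
                    spec, n_grid=predict_grid, n_time=predict_time
                ),
                "drift_zero_crossing_um3": spec.drift_zero_crossing(),
            }
        return pred

    predictions = _predict()

    @_stage("compare")
    def _compare():
        cmp: dict = {}
        if len(groups) == 2:
            a, b = groups
            t, p = estimation.compare_slopes(slow_moments[a], slow_moments[b])
            cmp["slope_interaction"] = {"t": t, "p": p}
            frac = estimation.elimination_by_dendrite(table)
            fa = frac.loc[frac["group"] == a, "fraction"]
            fb = frac.loc[frac["group"] == b, "fraction"]
            u = mannwhitneyu(fa, fb, alternative="two-sided")
            cmp["elimination_mannwhitney"] = {"U": float(u.statistic), "p": float(u.pvalue)}
            va = table.loc[(table["group"] == a) & ~table["eliminated"], "volume_um3"]
            vb = table.loc[(table["group"] == b) & ~table["eliminated"], "volume_um3"]
            d, p_ks = fp.distribution_comparison(va, vb)
            cmp["volume_ks"] = {"D": d, "p": p_ks}
            frac.to_csv(out / "elimination_by_dendrite.csv", index=False)
        return cmp

    comparisons = _compare()

    manifest = {
        "config": _jsonable(asdict(config)),
        "seed": config.seed,
        "fast_seed": fast_cfg.seed,
        "fast_fit": {"slope": fast_coeffs[0], "intercept": fast_coeffs[1]},
        "drift_fit": {"slope": drift_coeffs[0], "intercept": drift_coeffs[1]},
        "fitted_specs": {
            g: {**asdict(fitted[g]["spec"]), "slow_slope_ci": list(fitted[g]["slow_slope_ci"])}
            for g in groups
        },
        "predictions": predictions,
        "comparisons": comparisons,
        "artifacts": sorted(p.name for p in out.glob("*.csv")) + ["manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
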