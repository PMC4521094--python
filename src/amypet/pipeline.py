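"""End-to-end scenario orchestration.

``run_scenario`` executes the full chain — generate a calibrated synthetic
cohort and phantom, quantify the phantom, derive ROC cut-offs per age
group, classify amyloid positivity, harmonize the PIB cut-off onto the
Florbetapir scale, fit per-stratum Gaussian mixtures, and run the two-way
age x ApoE4 ANOVA per ROI — writing every intermediate table plus a
manifest (seeds, versions, SHA-256 of each output) so a rerun with the
same configuration is byte-identical. ``make_report`` renders the bundle
as a deterministic plain-text summary.

One top-level seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage can be re-run in
isolation with its own recorded seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .quant import (
    COMPOSITE_ROIS,
    compute_cctxr,
    compute_reference_value,
    compute_suvr_image,
    extract_roi_means,
)
from .synthdata import (
    CohortConfig,
    PhantomSpec,
    default_cohort_config,
    default_phantom_spec,
    default_roi_defs,
    generate_cohort,
    generate_phantom,
)
from .threshold import (
    LinearMap,
    classify_amyloid,
    convert_cutoff,
    optimal_cutoff,
    roc_curve,
)
from .mixture import fit_gaussian_mixture, select_model, test_normality
from .cohortstats import two_way_anova

__all__ = ["RunConfig", "run_scenario", "make_report", "stage_seeds"]

logger = logging.getLogger("amypet")

_STAGES = ("synthdata", "quant", "threshold", "mixture", "stats")


@dataclass
class RunConfig:
    """Configuration of one scenario run."""

    name: str = "published-calibration"
    seed: int = 0
    outdir: str | Path = "runs/default"
    cohort: CohortConfig | None = None  # None -> calibrated default
    phantom: PhantomSpec | None = None  # None -> default atlas phantom
    pib_cutoff: float = 1.42
    florbetapir_cutoff: float = 1.34
    tracer_map: LinearMap = field(
        default_factory=lambda: LinearMap(slope=1.13, intercept=-0.28, group="HC")
    )
    reference_statistic: str = "mean"  # whole-cerebellum convention
    mixture_restarts: int = 20
    ci_method: str = "delong"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in ("name", "seed", "outdir", "pib_cutoff", "florbetapir_cutoff",
                    "reference_statistic", "mixture_restarts", "ci_method"):
            if key in raw:
                kwargs[key] = raw[key]
        if "tracer_map" in raw:
            kwargs["tracer_map"] = LinearMap(**raw["tracer_map"])
        return cls(**kwargs)


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one deterministic sub-seed per pipeline stage from the top seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_scenario(config: RunConfig) -> dict[str, Any]:
    """Run every stage in order; returns the result bundle and writes all tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    bundle: dict[str, Any] = {"name": config.name, "seed": config.seed,
                              "stage_seeds": seeds}
    written: list[Path] = []

    def emit(name: str, obj) -> None:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False, float_format="%.10g")
        else:
            path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        written.append(path)

    stage = "synthdata"
    try:
        cohort_cfg = config.cohort or default_cohort_config(seed=seeds[stage])
        cohort = generate_cohort(cohort_cfg)
        emit("cohort.csv", cohort)
        bundle["cohort"] = cohort

        stage = "quant"
        spec = config.phantom or default_phantom_spec(
            noise_sd=0.05, smoothing_fwhm_mm=6.0, seed=seeds[stage]
        )
        vol = generate_phantom(spec)
        ref = compute_reference_value(vol, [spec.reference_label],
                                      config.reference_statistic)
        suvr = compute_suvr_image(vol, ref)
        rois = extract_roi_means(suvr, default_roi_defs())
        phantom_row = {
            "subject_id": "PHANTOM", "reference_value": ref,
            "reference_statistic": config.reference_statistic,
            **{f"suvr_{k}": v for k, v in rois.items()},
            "cctxr": compute_cctxr({r: rois[r] for r in COMPOSITE_ROIS}),
        }
        emit("phantom_suvr.csv", pd.DataFrame([phantom_row]))
        bundle["phantom"] = phantom_row

        stage = "threshold"
        roc_reports = {}
        for age_group in ("younger", "older"):
            sub = cohort[(cohort.age_group == age_group)
                         & cohort.diagnosis.isin(["HC", "AD"])]
            roc = roc_curve(sub.cctxr, sub.diagnosis, "AD",
                            ci_method=config.ci_method, seed=seeds[stage])
            cut, sens, spec_ = optimal_cutoff(roc)
            roc_reports[age_group] = {
                "auc": roc.auc, "auc_ci": list(roc.auc_ci), "cutoff": cut,
                "sensitivity": sens, "specificity": spec_,
            }
        emit("roc.json", roc_reports)
        bundle["roc"] = roc_reports

        flags, positivity = classify_amyloid(
            cohort.cctxr, config.florbetapir_cutoff,
            strata=cohort.diagnosis + "/" + cohort.age_group,
        )
        emit("positivity.csv", positivity)
        bundle["positivity"] = positivity

        exact, display = convert_cutoff(config.tracer_map, config.pib_cutoff)
        harmonized = {
            "pib_cutoff": config.pib_cutoff, "slope": config.tracer_map.slope,
            "intercept": config.tracer_map.intercept,
            "harmonized_cutoff": exact, "harmonized_cutoff_display": display,
        }
        emit("harmonized_cutoff.json", harmonized)
        bundle["harmonized_cutoff"] = harmonized

        stage = "mixture"
        fits = {}
        for (diag, age_group), sub in cohort.groupby(["diagnosis", "age_group"]):
            x = sub.cctxr.to_numpy()
            d, p_norm = test_normality(x, n_mc=2000, seed=seeds[stage])
            f1 = fit_gaussian_mixture(x, 1)
            f2 = fit_gaussian_mixture(x, 2, n_restarts=config.mixture_restarts,
                                      seed=seeds[stage])
            choice = select_model(f1, f2)
            best = choice.chosen
            fits[f"{diag}/{age_group}"] = {
                "n": int(len(x)), "ks_d": d, "ks_p": p_norm,
                "chosen_k": choice.k, "delta_bic": choice.delta_bic,
                "weights": best.weights.tolist(), "means": best.means.tolist(),
                "sds": best.sds.tolist(),
            }
        emit("mixture_fits.json", fits)
        bundle["mixture"] = fits

        stage = "stats"
        anova_rows = []
        roi_cols = ["cctxr"] + [c for c in cohort.columns if c.startswith("suvr_")]
        for diag in ("HC", "AD"):
            sub = cohort[cohort.diagnosis == diag]
            for col in roi_cols:
                t = two_way_anova(sub[col], sub.age_group, sub.apoe4.astype(str),
                                  names=("age_group", "apoe4"))
                for effect, row in t.effects.iterrows():
                    anova_rows.append({
                        "diagnosis": diag, "measure": col, "effect": effect,
                        "F": row["F"], "df_num": row["df_num"],
                        "df_den": row["df_den"], "p": row["p"],
                    })
        anova = pd.DataFrame(anova_rows)
        emit("anova.csv", anova)
        bundle["anova"] = anova
    except Exception as err:  # noqa: BLE001 - annotate with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "scenario": config.name, "seed": config.seed, "stage_seeds": seeds,
        "version": __version__,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    bundle["manifest"] = manifest
    return bundle


def _fmt(x: float, nd: int = 2) -> str:
    # half-even display rounding; stored values keep full precision
    return f"{round(float(x), nd):.{nd}f}"


def make_report(bundle: Mapping[str, Any]) -> str:
    """Deterministic plain-text summary of a (possibly partial) result bundle.

    Missing stages are listed explicitly rather than silently dropped.
    SUVR/CCTXR values display at 2 decimals, percentages as integers.
    """
    lines = [f"amypet scenario report: {bundle.get('name', '<unnamed>')}", ""]
    if "roc" in bundle:
        lines.append("== ROC (HC vs AD, CCTXR) ==")
        for grp, r in bundle["roc"].items():
            lines.append(
                f"  {grp}: AUC {r['auc']:.3f} "
                f"[{r['auc_ci'][0]:.3f}-{r['auc_ci'][1]:.3f}], "
                f"cutoff {_fmt(r['cutoff'])} "
                f"(sens {round(100 * r['sensitivity']):d} %, "
                f"spec {round(100 * r['specificity']):d} %)"
            )
    else:
        lines.append("== ROC: MISSING ==")
    if "positivity" in bundle:
        lines.append("== Amyloid positivity ==")
        for _, row in bundle["positivity"].iterrows():
            lines.append(
                f"  {row['stratum']}: {int(row['n_positive'])}/{int(row['n'])} "
                f"({round(row['pct_positive']):d} %)"
            )
    else:
        lines.append("== Positivity: MISSING ==")
    if "harmonized_cutoff" in bundle:
        h = bundle["harmonized_cutoff"]
        lines.append("== Cross-tracer harmonization ==")
        lines.append(
            f"  PIB cutoff {_fmt(h['pib_cutoff'])} -> Florbetapir "
            f"{_fmt(h['harmonized_cutoff_display'])} "
            f"(y = {h['slope']:g}x {h['intercept']:+g})"
        )
    else:
        lines.append("== Harmonization: MISSING ==")
    if "mixture" in bundle:
        lines.append("== Mixture decompositions (CCTXR) ==")
        for stratum, f in sorted(bundle["mixture"].items()):
            comps = ", ".join(
                f"{_fmt(m)}±{_fmt(s)} (w={w:.2f})"
                for w, m, s in zip(f["weights"], f["means"], f["sds"])
            )
            lines.append(
                f"  {stratum} (n={f['n']}): K={f['chosen_k']}, {comps}, "
                f"KS p={f['ks_p']:.3f}"
            )
    else:
        lines.append("== Mixture: MISSING ==")
    if "anova" in bundle:
        sig = bundle["anova"].query("p < 0.05")
        lines.append(f"== Two-way ANOVA: {len(sig)} significant effects ==")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['diagnosis']} {row['measure']} {row['effect']}: "
                f"F({int(row['df_num'])},{int(row['df_den'])})={row['F']:.2f}, "
                f"p={row['p']:.3g}"
            )
    else:
        lines.append("== ANOVA: MISSING ==")
    return "\n".join(lines) + "\n"
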