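"""End-to-end pipeline: phantoms/volumes -> imaging metrics -> cohort report.

``run_pipeline`` takes a configuration mapping and returns a JSON-ready
report.  It is deterministic given the configuration and seeds, and the
report serialises byte-identically (sorted keys, plain floats).

Config keys (all optional, but at least one stage must be requested):

``phantoms``
    list of phantom parameter mappings (see :class:`~pleurovol.phantom.PhantomSpec`);
    each is generated, segmented and burden-measured, and the measured
    metrics are reported next to the generator's ground truth.
``volumes``
    list of ``{"path": ..., "side": ..., "landmarks": [z1, z2]}`` entries
    naming NIfTI files to segment and measure.
``cohort_csv``
    path of a cohort table (one row per patient) to analyse.
``table2``
    if true, analyse the bundled published R2 cohort.
``seed``
    base seed; phantom entries without their own seed derive one from it.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import fixtures, recist, segmentation, stats
from .phantom import PhantomSpec, generate_phantom
from .volume import read_volume

__all__ = ["run_pipeline", "report_to_json", "r2_cohort_report"]

log = logging.getLogger("pleurovol")

#: continuous predictors screened for the logistic model when a full
#: two-group cohort is supplied
DEFAULT_SCREENING = ["tlc_pct", "ipsilateral_volume_cm3", "diff_pct", "burden_mm"]


def _round(x, nd=4):
    return float(np.round(float(x), nd))


def r2_cohort_report(cohort: pd.DataFrame) -> dict:
    """Descriptive reproduction on a single-outcome (R2) cohort: medians
    with IQR, cut-off classification counts, and the reconstructed
    contralateral volumes."""
    rep: dict = {"n": int(len(cohort))}
    for colname in ("tlc_pct", "burden_mm", "ipsilateral_volume_cm3", "diff_pct"):
        med, q1, q3 = stats.median_iqr(cohort[colname])
        rep[colname] = {"median": _round(med), "q1": _round(q1), "q3": _round(q3)}
    rec = fixtures.reconstruct_contralateral(cohort)
    med, q1, q3 = stats.median_iqr(rec["diff_cm3"])
    rep["reconstructed_diff_cm3"] = {"median": _round(med), "q1": _round(q1), "q3": _round(q3)}
    counts = stats.classify_at_cutoffs(cohort)
    counts["volume_below_1794"] = int((cohort["ipsilateral_volume_cm3"] < 1794).sum())
    counts["diff_pct_above_46_22"] = int((cohort["diff_pct"] > 46.22).sum())
    rep["cutoff_counts"] = counts
    return rep


def _two_group_report(cohort: pd.DataFrame) -> dict:
    rep: dict = {"n": int(len(cohort))}
    groups = {k: v for k, v in cohort.groupby("outcome")}
    if set(groups) != {"MCR", "R2"}:
        raise ValueError("two-group analysis needs outcomes MCR and R2")
    rep["groups"] = {}
    rep["mann_whitney_p"] = {}
    rep["cutoffs"] = {}
    directions = {"tlc_pct": "below", "ipsilateral_volume_cm3": "below",
                  "diff_pct": "above", "burden_mm": "above"}
    present = [c for c in DEFAULT_SCREENING if c in cohort.columns]
    for colname in present:
        desc = {}
        for g, sub in groups.items():
            med, q1, q3 = stats.median_iqr(sub[colname])
            desc[g] = {"median": _round(med), "q1": _round(q1), "q3": _round(q3)}
        rep["groups"][colname] = desc
        _, p = stats.mann_whitney(groups["MCR"][colname], groups["R2"][colname])
        rep["mann_whitney_p"][colname] = _round(p, 6)
        cut = stats.roc_cutoff(cohort[colname], cohort["outcome"] == "R2",
                               direction=directions[colname], predictor=colname)
        rep["cutoffs"][colname] = {
            "direction": cut.direction, "cutoff": _round(cut.cutoff),
            "auc": _round(cut.auc), "sensitivity": _round(cut.sensitivity),
            "specificity": _round(cut.specificity),
        }
    selected = stats.screen_univariable(cohort, present)
    rep["univariable_selected"] = selected
    if selected:
        multi = stats.logistic_multivariable(cohort, selected)
        rep["multivariable"] = {
            name: {
                "odds_ratio": _round(e.odds_ratio),
                "ci": [_round(e.ci_low), _round(e.ci_high)],
                "p": _round(e.p_value, 6),
            }
            for name, e in multi.effects.items()
        } | {"separation": multi.separation}
    return rep


def _imaging_metrics(vol, landmarks) -> dict:
    seg = segmentation.segment_lungs(vol)
    masks = {"left": seg.left_mask, "right": seg.right_mask}
    entry = {k: _round(v) for k, v in seg.as_dict().items() if isinstance(v, float)}
    entry["affected_side"] = seg.affected_side
    if landmarks is not None:
        burden = recist.measure_burden(vol, masks, tuple(landmarks))
        entry["burden_mm"] = _round(burden.burden_mm)
        entry["per_level_max_mm"] = {k: _round(v) for k, v in burden.per_level_max_mm.items()}
    return entry


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Run every configured stage and return the merged report."""
    if not config or not any(k in config for k in ("phantoms", "volumes", "cohort_csv", "table2")):
        raise ValueError(
            "empty configuration: provide 'phantoms', 'volumes', 'cohort_csv' or 'table2'"
        )
    base_seed = int(config.get("seed", seed if seed is not None else 0))
    report: dict = {"seed": base_seed}

    if config.get("phantoms"):
        entries = []
        for i, params in enumerate(config["phantoms"]):
            params = dict(params)
            params.setdefault("seed", (base_seed * 1000 + i) % (2**31))
            landmarks = params.pop("landmarks", None)
            spec = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in params.items()})
            log.info("phantom %d: generating (%s)", i, spec.affected_side)
            vol, truth = generate_phantom(spec)
            if landmarks is None:
                landmarks = spec.level_planes
            try:
                entry = _imaging_metrics(vol, landmarks)
            except Exception as exc:
                raise RuntimeError(f"stage=imaging phantom={i}: {exc}") from exc
            entry["truth"] = {
                "left_volume_cm3": _round(truth.true_lung_volume_cm3["left"]),
                "right_volume_cm3": _round(truth.true_lung_volume_cm3["right"]),
                "burden_mm": _round(truth.true_burden_mm),
            }
            entries.append(entry)
        report["phantoms"] = entries

    if config.get("volumes"):
        entries = []
        for i, v in enumerate(config["volumes"]):
            log.info("volume %d: %s", i, v["path"])
            vol = read_volume(v["path"], affected_side=v.get("side", "unknown"))
            try:
                entries.append(_imaging_metrics(vol, v.get("landmarks")))
            except Exception as exc:
                raise RuntimeError(f"stage=imaging volume={v['path']}: {exc}") from exc
        report["volumes"] = entries

    cohort = None
    if config.get("table2"):
        cohort = fixtures.load_table2()
    elif config.get("cohort_csv"):
        cohort = pd.read_csv(config["cohort_csv"])
    if cohort is not None:
        try:
            if "outcome" in cohort.columns and cohort["outcome"].nunique() > 1:
                report["cohort"] = _two_group_report(cohort)
            else:
                report["cohort"] = r2_cohort_report(cohort)
        except Exception as exc:
            raise RuntimeError(f"stage=cohort-stats: {exc}") from exc
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialisation: identical reports give identical bytes."""
    return json.dumps(report, sort_keys=True, indent=2)
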