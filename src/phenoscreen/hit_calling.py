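"""Well triage, duplicate-run hit calling, dose validation and summaries.

A compound well is a hit when its Mahalanobis distance to the active-control
model lies more than ``k_sd`` (default 1) standard deviations *below* the
mean of the negative-control wells' distances — i.e. it looks like the +DOX
phenotype — in **every** replicate, and no replicate triages the well as
dead (too few objects) or disparate (far from both control phenotypes).
An alternative reading of the 1-SD rule (distance to the NC model more than
1 SD above the NC wells' self-distance) is available behind
``rule="nc_distance"`` but is not the default.

Validated hits must pass at ``m_consecutive`` (default 2) consecutive
concentrations of an 8-point range in both replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import WellRole

TRIAGE_DEAD = "dead"
TRIAGE_DISPARATE = "disparate"
TRIAGE_AC_LIKE = "ac_like"
TRIAGE_NC_LIKE = "nc_like"
TRIAGE_CLASSES = (TRIAGE_DEAD, TRIAGE_DISPARATE, TRIAGE_AC_LIKE, TRIAGE_NC_LIKE)


@dataclass(frozen=True)
class TriageConfig:
    min_objects: int = 5
    disparate_quantile: float = 0.95


@dataclass(frozen=True)
class HitRuleConfig:
    k_sd: float = 1.0
    rule: str = "ac_distance"  # or "nc_distance"


def triage_well(
    mhd_ac: float,
    mhd_nc: float,
    object_count: float | None,
    nc_mhd_ac_q: float,
    ac_mhd_nc_q: float,
    config: TriageConfig = TriageConfig(),
) -> str:
    """Assign one of {dead, disparate, ac_like, nc_like} to a scored well.

    ``nc_mhd_ac_q`` / ``ac_mhd_nc_q`` are the disparate-phenotype quantiles
    of the plate's control scores (Q95 of NC wells' MHD-to-AC and of AC
    wells' MHD-to-NC).  ``object_count=None`` disables the dead check (used
    when no imaging-derived count is available).
    """
    if not (np.isfinite(nc_mhd_ac_q) and np.isfinite(ac_mhd_nc_q)):
        raise ValueError("missing control score distributions for triage")
    if object_count is not None and object_count < config.min_objects:
        return TRIAGE_DEAD
    if mhd_ac > nc_mhd_ac_q and mhd_nc > ac_mhd_nc_q:
        return TRIAGE_DISPARATE
    return TRIAGE_AC_LIKE if mhd_ac <= mhd_nc else TRIAGE_NC_LIKE


def triage_plate(
    scores: pd.DataFrame,
    object_counts: pd.Series | None = None,
    config: TriageConfig = TriageConfig(),
) -> pd.Series:
    """Triage every well of a scored plate (columns well/role/mhd_ac/mhd_nc)."""
    roles = scores["role"]
    nc = scores.loc[roles == WellRole.NEGATIVE_CONTROL.value, "mhd_ac"]
    ac = scores.loc[roles == WellRole.ACTIVE_CONTROL.value, "mhd_nc"]
    if nc.empty or ac.empty:
        raise ValueError("missing control score distributions for triage")
    nc_q = float(nc.quantile(config.disparate_quantile))
    ac_q = float(ac.quantile(config.disparate_quantile))
    out = []
    for i, row in scores.reset_index(drop=True).iterrows():
        count = None
        if object_counts is not None:
            count = float(object_counts.iloc[i])
        out.append(
            triage_well(row["mhd_ac"], row["mhd_nc"], count, nc_q, ac_q, config)
        )
    return pd.Series(out, index=scores.index, name="triage")


def replicate_pass_threshold(
    scores: pd.DataFrame, config: HitRuleConfig = HitRuleConfig()
) -> float:
    """The plate's hit threshold from its NC wells' score distribution."""
    col = "mhd_ac" if config.rule == "ac_distance" else "mhd_nc"
    nc = scores.loc[scores["role"] == WellRole.NEGATIVE_CONTROL.value, col]
    if len(nc) < 2:
        raise ValueError("need >= 2 NC wells to set the hit threshold")
    if config.rule == "ac_distance":
        return float(nc.mean() - config.k_sd * nc.std(ddof=1))
    return float(nc.mean() + config.k_sd * nc.std(ddof=1))


def _passes(value: float, threshold: float, config: HitRuleConfig) -> bool:
    # strict inequality: a well exactly at the threshold is not a hit
    if config.rule == "ac_distance":
        return bool(value < threshold)
    return bool(value > threshold)


def call_hits(
    replicate_scores: dict[int, pd.DataFrame],
    triage: dict[int, pd.Series] | None = None,
    config: HitRuleConfig = HitRuleConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Combine per-replicate scores into final duplicate-run hit calls.

    ``replicate_scores`` maps replicate id to a scored plate table (columns
    well, role, compound_id, mhd_ac, mhd_nc).  ``triage``, when given, maps
    replicate id to a triage Series aligned with that table; a final hit
    must then be triaged ac_like in every replicate.  Compounds present in
    fewer than two replicates are excluded with a logged finding.

    Returns ``(hit table, findings)``.
    """
    if not replicate_scores:
        raise ValueError("no replicate scores given")
    findings: list[str] = []
    per_rep: dict[int, pd.DataFrame] = {}
    for rep, scores in replicate_scores.items():
        thr = replicate_pass_threshold(scores, config)
        comp = scores[scores["role"] == WellRole.COMPOUND.value].reset_index()
        col = "mhd_ac" if config.rule == "ac_distance" else "mhd_nc"
        rec = pd.DataFrame(
            {
                "compound_id": comp["compound_id"],
                "score": comp[col],
                "passed": [_passes(v, thr, config) for v in comp[col]],
            }
        )
        if triage is not None:
            rec["triage"] = triage[rep].loc[comp["index"]].to_numpy()
        else:
            rec["triage"] = TRIAGE_AC_LIKE
        dup = rec["compound_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"replicate {rep}: compound scored in multiple wells "
                f"({rec.loc[dup, 'compound_id'].iloc[0]}); split by concentration first"
            )
        per_rep[rep] = rec.set_index("compound_id")

    all_compounds = sorted(set().union(*(r.index for r in per_rep.values())))
    rows = []
    for cid in all_compounds:
        present = [rep for rep in sorted(per_rep) if cid in per_rep[rep].index]
        if len(present) < 2:
            findings.append(f"compound_in_single_replicate:{cid}")
            continue
        passes = {rep: bool(per_rep[rep].loc[cid, "passed"]) for rep in present}
        triages = {rep: str(per_rep[rep].loc[cid, "triage"]) for rep in present}
        final = all(passes.values()) and all(
            t == TRIAGE_AC_LIKE for t in triages.values()
        )
        rows.append(
            {
                "compound_id": cid,
                "n_replicates": len(present),
                "replicate_passes": tuple(passes[r] for r in present),
                "replicate_triage": tuple(triages[r] for r in present),
                "final_hit": final,
            }
        )
    hits = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "n_replicates", "replicate_passes",
            "replicate_triage", "final_hit",
        ],
    )
    return hits, findings


def validate_hits(
    pass_table: pd.DataFrame,
    n_concentrations: int = 8,
    m_consecutive: int = 2,
) -> pd.DataFrame:
    """Dose-range validation of hit compounds.

    ``pass_table`` has one row per (compound_id, concentration_uM,
    replicate) with a boolean ``passed`` column.  A compound is validated
    when at least ``m_consecutive`` consecutive concentrations pass in
    *both* replicates at the same concentrations (replicate-wise AND, then
    longest run).  Missing concentration points raise.
    """
    required = {"compound_id", "concentration_uM", "replicate", "passed"}
    missing_cols = required - set(pass_table.columns)
    if missing_cols:
        raise ValueError(f"pass table missing columns {sorted(missing_cols)}")
    rows = []
    for cid, grp in pass_table.groupby("compound_id", sort=True):
        pivot = grp.pivot_table(
            index="concentration_uM", columns="replicate", values="passed",
            aggfunc="first",
        ).sort_index()
        if len(pivot) != n_concentrations or pivot.isna().any().any():
            raise ValueError(
                f"compound {cid}: expected {n_concentrations} concentrations "
                f"in every replicate, got {len(pivot)} rows"
            )
        if pivot.shape[1] < 2:
            raise ValueError(f"compound {cid}: fewer than 2 replicates")
        combined = pivot.astype(bool).all(axis=1).to_numpy()
        best = run = 0
        for v in combined:
            run = run + 1 if v else 0
            best = max(best, run)
        rows.append(
            {
                "compound_id": cid,
                "concentrations": tuple(pivot.index),
                "n_consecutive_pass": best,
                "validated": best >= m_consecutive,
            }
        )
    return pd.DataFrame(
        rows, columns=["compound_id", "concentrations", "n_consecutive_pass", "validated"]
    )


def summarize_target_classes(
    hits: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Hit counts and fractions per annotated target class, best first.

    Hit compounds missing from the annotation table are counted under
    ``"unknown"`` with a warning.  Fractions sum to 1 over classes.
    """
    final = hits
    if "final_hit" in hits.columns and len(hits):
        final = hits[hits["final_hit"].astype(bool)]
    if final.empty:
        return pd.DataFrame(columns=["target_class", "n_hits", "fraction"])
    lookup = dict(
        zip(annotation["compound_id"].astype(str), annotation["target_class"].astype(str))
    )
    classes = []
    for cid in final["compound_id"]:
        if str(cid) in lookup:
            classes.append(lookup[str(cid)])
        else:
            warnings.warn(f"hit compound {cid} not annotated; counted as 'unknown'")
            classes.append("unknown")
    counts = pd.Series(classes).value_counts()
    out = pd.DataFrame(
        {
            "target_class": counts.index,
            "n_hits": counts.to_numpy(),
            "fraction": counts.to_numpy() / counts.sum(),
        }
    )
    return out.reset_index(drop=True)
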