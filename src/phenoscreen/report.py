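"""Human-readable Markdown run reports.

Reports render existing run artifacts (QC JSON, hit CSV, class summary,
effective config) without recomputing anything, so regenerating a report is
idempotent.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml


class IncompleteRunError(FileNotFoundError):
    pass


def _table(df: pd.DataFrame) -> str:
    if df.empty:
        return "_(none)_\n"
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    rows = [
        "| " + " | ".join(str(v) for v in rec) + " |"
        for rec in df.itertuples(index=False)
    ]
    return "\n".join([header, sep, *rows]) + "\n"


def render_report(run_dir: str | Path) -> str:
    """Consolidated Markdown report of a completed analysis run."""
    run = Path(run_dir)
    summary_path = run / "summary.json"
    if not summary_path.exists():
        raise IncompleteRunError(f"no summary.json in {run}")
    summary = json.loads(summary_path.read_text())

    parts = [f"# Screen analysis report: {summary.get('run_id', run.name)}\n"]

    config_path = run / "config.yaml"
    if config_path.exists():
        parts.append("## Effective configuration\n")
        parts.append("```yaml\n" + config_path.read_text().strip() + "\n```\n")

    parts.append("## Plate quality control\n")
    qc = pd.DataFrame(summary.get("plates", []))
    if not qc.empty:
        qc = qc[["plate_id", "replicate_id", "zprime", "qc_pass", "features_used"]]
        qc["zprime"] = qc["zprime"].map(lambda z: f"{z:.3f}")
        qc["features_used"] = qc["features_used"].map(lambda f: ", ".join(f))
    parts.append(_table(qc))
    parts.append(
        f"\nQC floor for hit-calling eligibility: Z' >= "
        f"{summary.get('qc_floor')}\n"
    )

    parts.append("\n## Hit calling\n")
    parts.append(
        f"- compounds assessed: {summary.get('n_compounds', 0)}\n"
        f"- final hits: {summary.get('n_hits', 0)}\n"
        f"- hit rule: {summary.get('hit_rule')}\n"
    )
    hits_path = run / "hits.csv"
    if hits_path.exists():
        hits = pd.read_csv(hits_path)
        final = hits[hits["final_hit"].astype(bool)] if len(hits) else hits
        parts.append("\n### Final hits\n")
        parts.append(_table(final[["compound_id", "replicate_passes", "replicate_triage"]]))

    classes_path = run / "target_classes.csv"
    if classes_path.exists():
        parts.append("\n## Target classes of hits\n")
        cls = pd.read_csv(classes_path)
        if not cls.empty:
            cls["fraction"] = cls["fraction"].map(lambda f: f"{f:.2f}")
        parts.append(_table(cls))

    if "recall" in summary:
        parts.append("\n## Recovery vs. ground truth\n")
        parts.append(
            f"- recall: {summary['recall']:.3f}\n"
            f"- false discovery proportion: {summary['fdp']:.3f}\n"
            f"- planted actives: {summary.get('n_true_actives')}\n"
        )

    parts.append("\n## Findings\n")
    findings = summary.get("findings", [])
    parts.append("".join(f"- {f}\n" for f in findings) if findings else "_(none)_\n")
    return "\n".join(parts)


def write_report(run_dir: str | Path) -> Path:
    out = Path(run_dir) / "report.md"
    out.write_text(render_report(run_dir))
    return out


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config_yaml(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True, default_flow_style=False)
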