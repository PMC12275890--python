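"""End-to-end orchestration: read -> preprocess -> stratify -> test -> RI report.

Replaces an interactive GUI with reproducible batch artifacts: per-stratum
diagnosis tables, cluster tables, removed-result manifests, and a
machine-readable RI report comparing GD, DD and (optionally) DD-with-
clustering reference intervals per stratum.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_stratum_codes, cluster_table_and_dd
from .differential import (
    DiagnosisTable,
    build_diagnosis_table,
    differential_distribution,
)
from .io import (
    Dialect,
    Stratum,
    preprocess,
    read_results,
    stratify,
    write_audit,
)
from .ri import (
    InsufficientSampleError,
    DegenerateDistributionError,
    ReferenceInterval,
    compare_ris,
    ri_for_distribution,
)

logger = logging.getLogger("ddri")

RI_REPORT_COLUMNS = [
    "sex", "age_lo", "age_hi", "distribution",
    "lower", "ci_lower_lo", "ci_lower_hi",
    "upper", "ci_upper_lo", "ci_upper_hi",
    "n_used", "n_input",
    "verdict_lower", "verdict_upper", "delta_lower", "delta_upper",
]


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, with the method's defaults."""

    input_path: str = ""
    output_dir: str = "ddm_run"
    delimiter: str = ","
    analyte: str = "potassium"
    value_min: float = 0.5
    value_max: float = 12.0
    band_width: int = 10
    alpha: float = 0.05
    normality_alpha: float = 0.05
    min_n: int = 6
    threshold_on: str = "q"
    compare_to_complement: bool = False
    strict_code_filter: bool = False
    clustering: bool = True
    k: int = 800
    cluster_method: str = "hierarchical"
    cluster_linkage: str = "average"
    distance_mode: str = "complement"
    embedding_d: int = 100
    embedding_window: int = 5
    embedding_epochs: int = 20
    embedding_min_count: int = 6
    ri_mode: str = "parametric"
    trim_z: float = 1.96
    tol: float = 1e-4
    max_iter: int = 50
    seed: int = 0
    skip_failing_strata: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ri_row(
    stratum: Stratum,
    label: str,
    ri: ReferenceInterval | None,
    gd_ri: ReferenceInterval | None,
) -> dict:
    row = {
        "sex": stratum.sex, "age_lo": stratum.age_lo, "age_hi": stratum.age_hi,
        "distribution": label,
    }
    if ri is None:
        return row | {c: "" for c in RI_REPORT_COLUMNS[4:]}
    row |= {
        "lower": ri.lower, "ci_lower_lo": ri.ci_lower[0], "ci_lower_hi": ri.ci_lower[1],
        "upper": ri.upper, "ci_upper_lo": ri.ci_upper[0], "ci_upper_hi": ri.ci_upper[1],
        "n_used": ri.n_used, "n_input": ri.n_input,
    }
    if gd_ri is not None and ri is not gd_ri:
        lo_v, up_v = compare_ris(gd_ri, ri)
        row |= {
            "verdict_lower": lo_v.verdict, "verdict_upper": up_v.verdict,
            "delta_lower": lo_v.delta, "delta_upper": up_v.delta,
        }
    else:
        row |= {"verdict_lower": "", "verdict_upper": "", "delta_lower": 0.0, "delta_upper": 0.0}
    return row


def run_ddm(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Writes: preprocessing audit, per-code diagnosis tables, removed-result
    manifests, cluster assignments and cluster tables (when clustering is
    enabled), the RI report (GD / DD / DD_clustered rows per stratum) and a
    run log with all effective parameters.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    dialect = Dialect(delimiter=config.delimiter)
    results, rejects = read_results(config.input_path, dialect)
    kept, audit = preprocess(
        results,
        value_min=config.value_min,
        value_max=config.value_max,
        strict_code_filter=config.strict_code_filter,
    )
    write_audit(audit, out / "audit.csv")
    if rejects:
        pd.DataFrame(rejects).to_csv(out / "rejects.csv", index=False)
    strata = stratify(kept, band_width=config.band_width)

    diag_frames, cluster_frames, manifest_frames, assign_frames = [], [], [], []
    ri_rows = []
    stratum_log = []
    for stratum in strata:
        entry: dict = {"stratum": stratum.label, "n": len(stratum)}
        if len(stratum) == 0:
            entry["status"] = "empty"
            stratum_log.append(entry)
            continue
        table = build_diagnosis_table(
            stratum,
            min_n=config.min_n,
            alpha=config.alpha,
            normality_alpha=config.normality_alpha,
            seed=config.seed,
            compare_to_complement=config.compare_to_complement,
            threshold_on=config.threshold_on,
        )
        dd = differential_distribution(stratum, table)
        diag_frames.append(table.to_frame())
        mf = dd.manifest_frame()
        mf.insert(0, "stratum", stratum.label)
        manifest_frames.append(mf)
        entry["removed_per_code"] = dd.removed_count
        entry["removal_fraction"] = round(dd.removal_fraction, 4)

        dd_clustered = None
        if config.clustering:
            try:
                _, clustering = cluster_stratum_codes(
                    stratum,
                    k=config.k,
                    method=config.cluster_method,
                    linkage=config.cluster_linkage,
                    seed=config.seed,
                    distance_mode=config.distance_mode,
                    embedding_params={
                        "d": config.embedding_d,
                        "window": config.embedding_window,
                        "epochs": config.embedding_epochs,
                        "min_count": config.embedding_min_count,
                    },
                )
                ctable, dd_clustered = cluster_table_and_dd(
                    stratum, clustering,
                    min_n=config.min_n, alpha=config.alpha,
                    normality_alpha=config.normality_alpha, seed=config.seed,
                    compare_to_complement=config.compare_to_complement,
                    threshold_on=config.threshold_on,
                )
                cf = ctable.to_frame()
                cluster_frames.append(cf)
                af = clustering.to_frame()
                af.insert(0, "stratum", stratum.label)
                assign_frames.append(af)
            except ValueError as exc:
                logger.warning("clustering skipped for %s: %s", stratum.label, exc)
                entry["clustering"] = f"skipped: {exc}"

        gd_ri = None
        for label, values in (
            ("GD", stratum.gd_values),
            ("DD", dd.dd_values),
            ("DD_clustered", None if dd_clustered is None else dd_clustered.dd_values),
        ):
            if values is None:
                continue
            try:
                ri = ri_for_distribution(
                    values, mode=config.ri_mode, trim_z=config.trim_z,
                    tol=config.tol, max_iter=config.max_iter,
                )
            except (InsufficientSampleError, DegenerateDistributionError) as exc:
                logger.warning("RI for %s/%s skipped: %s", stratum.label, label, exc)
                entry[f"ri_{label}"] = f"skipped: {exc}"
                if not config.skip_failing_strata:
                    raise
                ri = None
            if label == "GD":
                gd_ri = ri
            ri_rows.append(_ri_row(stratum, label, ri, gd_ri))
        entry.setdefault("status", "ok")
        stratum_log.append(entry)

    _concat(diag_frames).to_csv(out / "diagnosis_tables.csv", index=False)
    _concat(manifest_frames).to_csv(out / "removed_manifest.csv", index=False)
    if config.clustering:
        _concat(cluster_frames).to_csv(out / "cluster_tables.csv", index=False)
        _concat(assign_frames).to_csv(out / "cluster_assignments.csv", index=False)
    pd.DataFrame(ri_rows, columns=RI_REPORT_COLUMNS).to_csv(
        out / "ri_report.csv", index=False
    )
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": config.to_dict(),
                "n_read": len(results),
                "n_rejected_rows": len(rejects),
                "n_kept": len(kept),
                "audit": dict(audit.removed),
                "codes_dropped": audit.codes_dropped,
                "strata": stratum_log,
            },
            fh,
            indent=2,
        )
    return out


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    frames = [f for f in frames if not f.empty]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def summarize(run_dir: str | Path, plot: bool = False) -> Path:
    """Write a human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    report_path = run_dir / "ri_report.csv"
    if not report_path.exists():
        raise FileNotFoundError(f"expected RI report at {report_path}")
    report = pd.read_csv(report_path)
    log_path = run_dir / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}

    lines = ["# DDM run summary", ""]
    if log:
        lines += [
            f"- package version: {log.get('version')}",
            f"- seed: {log.get('config', {}).get('seed')}",
            f"- records read: {log.get('n_read')}, kept after preprocessing: {log.get('n_kept')}",
            "",
        ]
    lines += [
        "| stratum | distribution | n_used/n_input | RI | verdicts (lo/up) | delta (lo/up) |",
        "|---|---|---|---|---|---|",
    ]
    for _, r in report.iterrows():
        if pd.isna(r.get("lower")) or r.get("lower") == "":
            ri_txt, n_txt, verdicts, deltas = "(skipped)", "-", "-", "-"
        else:
            ri_txt = f"[{float(r['lower']):.3f}, {float(r['upper']):.3f}]"
            n_txt = f"{int(r['n_used'])}/{int(r['n_input'])}"
            if isinstance(r["verdict_lower"], str) and r["verdict_lower"]:
                verdicts = f"{r['verdict_lower']}/{r['verdict_upper']}"
                deltas = f"{float(r['delta_lower']):+.3f}/{float(r['delta_upper']):+.3f}"
            else:
                verdicts, deltas = "-", "-"
        lines.append(
            f"| {r['sex']} {int(r['age_lo'])}-{int(r['age_hi'])} | {r['distribution']} "
            f"| {n_txt} | {ri_txt} | {verdicts} | {deltas} |"
        )
    out = run_dir / "summary.md"
    out.write_text("\n".join(lines) + "\n")

    if plot:
        _plot_run(run_dir, report)
    return out


def _plot_run(run_dir: Path, report: pd.DataFrame) -> None:
    """Histogram of GD vs DD per stratum with RI limits as vertical lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest = run_dir / "removed_manifest.csv"
    if not manifest.exists():  # pragma: no cover - defensive
        logger.warning("no removed-results manifest; skipping plot")
        return
    strata = report[["sex", "age_lo", "age_hi"]].drop_duplicates()
    n = len(strata)
    fig, axes = plt.subplots(max(1, (n + 1) // 2), 2, figsize=(11, 2.4 * max(1, (n + 1) // 2)))
    axes = np.atleast_1d(axes).ravel()
    for ax, (_, srow) in zip(axes, strata.iterrows()):
        sub = report[
            (report.sex == srow.sex)
            & (report.age_lo == srow.age_lo)
            & (report.distribution.isin(["GD", "DD"]))
        ]
        for _, r in sub.iterrows():
            if r["lower"] == "" or pd.isna(r["lower"]):
                continue
            color = "tab:blue" if r.distribution == "GD" else "tab:orange"
            ax.axvline(float(r["lower"]), color=color, ls="--", lw=1)
            ax.axvline(float(r["upper"]), color=color, ls="-", lw=1,
                       label=f"{r.distribution} RI")
        ax.set_title(f"{srow.sex} {int(srow.age_lo)}-{int(srow.age_hi)}", fontsize=8)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(run_dir / "ri_limits.png", dpi=100)
    plt.close(fig)
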