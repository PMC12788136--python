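"""Serialisation and plotting of metric reports.

The TSV layout mirrors the per-joint evaluation tables of hand-tracking
studies: one row per joint class plus a pooled Overall row, columns
``Joint | Method | <metric> ...`` with cells ``mean ± std`` and undefined
cells spelled ``N/A``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .hand import AngleTrajectory
from .metrics import APCKCurve, MeanStd, MetricReport

#: column headings per metric key
METRIC_HEADINGS = {
    "mpjae": "MPJAE (°)",
    "apck@5": "APCK@5",
    "apck@10": "APCK@10",
    "apck_auc": "APCK AUC",
    "mpjpe": "MPJPE (mm)",
    "mpjave": "MPJAVE (°/s)",
    "sparc_error": "Angular SPARC Error",
}


def _cell(ms: MeanStd | None, metric: str, decimals: int = 2) -> str:
    if ms is None:
        return "N/A"
    if metric.startswith("apck"):
        # a fraction of binary per-sample hits; spread is uninformative
        return f"{ms.mean:.3f}"
    return f"{ms.mean:.{decimals}f} ± {ms.std:.{decimals}f}"


def report_to_tsv(report: MetricReport, decimals: int = 2) -> str:
    metrics = report.metrics()
    header = ["Joint", "Method"] + [METRIC_HEADINGS.get(m, m)
                                    for m in metrics]
    lines = ["\t".join(header)]
    for cls in report.classes:
        row = [cls, report.method]
        for m in metrics:
            row.append(_cell(report.cells[m].get(cls), m, decimals))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def report_to_dict(report: MetricReport) -> dict:
    out = {"method": report.method, "classes": list(report.classes),
           "metrics": {}}
    for m, row in report.cells.items():
        out["metrics"][m] = {
            cls: (None if ms is None else
                  {"mean": ms.mean, "std": ms.std, "n": ms.n,
                   "units": ms.units})
            for cls, ms in row.items()}
    return out


def write_report(report: MetricReport, out_dir,
                 stem: str = "report") -> tuple[Path, Path]:
    """Write the report as ``<stem>.json`` and ``<stem>.tsv``; returns both
    paths.  Output is deterministic (sorted keys, no timestamps)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jpath = out_dir / f"{stem}.json"
    tpath = out_dir / f"{stem}.tsv"
    jpath.write_text(json.dumps(report_to_dict(report), sort_keys=True,
                                indent=1) + "\n")
    tpath.write_text(report_to_tsv(report))
    return jpath, tpath


def rom_to_tsv(rom_table, decimals: int = 1) -> str:
    """Long-format TSV of a :class:`handkin.kinematics.RomTable`."""
    lines = ["finger\tjoint\tmin_deg\tmax_deg\tn_frames\tn_missing"]
    for (finger, joint), bounds in rom_table.rom.items():
        lo = "N/A" if bounds is None else f"{bounds[0]:.{decimals}f}"
        hi = "N/A" if bounds is None else f"{bounds[1]:.{decimals}f}"
        miss = rom_table.n_missing.get((finger, joint), 0)
        lines.append(f"{finger}\t{joint}\t{lo}\t{hi}\t"
                     f"{rom_table.n_frames}\t{miss}")
    return "\n".join(lines) + "\n"


def plot_apck_curve(curve: APCKCurve, path, label: str = "model") -> Path:
    """APCK score against the error threshold, annotated with the AUC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.thresholds, curve.scores,
            label=f"{label} (AUC={curve.auc:.3f})")
    ax.set_xlabel("error threshold (°)")
    ax.set_ylabel("APCK")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_angle_curves(pred: AngleTrajectory, gt: AngleTrajectory,
                      finger: str, path) -> Path:
    """Per-joint angle-time curves of one finger, prediction vs ground
    truth."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joints = [j for (f, j) in gt.joints if f == finger]
    fig, axes = plt.subplots(len(joints), 1, figsize=(6, 2.2 * len(joints)),
                             sharex=True, squeeze=False)
    t = gt.timestamps
    for ax, joint in zip(axes[:, 0], joints):
        ax.plot(t, gt.column(finger, joint), label="ground truth", lw=1.5)
        ax.plot(pred.timestamps, pred.column(finger, joint),
                label="prediction", lw=1.0)
        ax.set_ylabel(f"{joint.upper()} (°)")
    axes[-1, 0].set_xlabel("time (s)")
    axes[0, 0].legend(loc="lower right", fontsize=8)
    fig.suptitle(f"{finger} joint angles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
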