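"""Benchmark reporting: JSON + Markdown summaries and SVG figures."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .benchmark import (SweepResult, regression_with_slope_compare,
                        severity_accuracy_groups)

__all__ = ["sweep_report", "sweep_summary_dict"]


def sweep_summary_dict(sweep: SweepResult) -> dict:
    """JSON-ready digest of a fidelity sweep."""
    out = {
        "n_analyzed": sweep.n_analyzed,
        "excluded": [{"case_id": c, "reason": r} for c, r in sweep.excluded],
        "per_fidelity": sweep.summary.to_dict(orient="records"),
        "adjacent_duration": sweep.adjacent_duration.to_dict(orient="records"),
        "adjacent_accuracy": sweep.adjacent_accuracy.to_dict(orient="records"),
        "bland_altman": {
            str(p): {"bias": ba.bias, "loa_low": ba.loa_low,
                     "loa_high": ba.loa_high, "n": ba.n}
            for p, ba in sweep.bland_altman.items()},
        "concordance": {
            str(p): {"percent": c.percent, "discordant": list(c.discordant)}
            for p, c in sweep.concordance.items()},
    }
    if sweep.n_analyzed >= 3:
        reg = regression_with_slope_compare(severity_accuracy_groups(sweep))
        out["severity_accuracy"] = {
            "per_fidelity": reg.per_group.reset_index().to_dict(orient="records"),
            "slope_equality_p": reg.p_value,
        }
    return out


def sweep_report(sweep: SweepResult, outdir) -> dict:
    """Write JSON + Markdown + SVG figures for a sweep; returns the digest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = sweep_summary_dict(sweep)
    (outdir / "summary.json").write_text(json.dumps(digest, indent=2))
    sweep.records.to_csv(outdir / "records.csv", index=False)
    (outdir / "summary.md").write_text(_markdown(sweep, digest))
    _figures(sweep, outdir)
    return digest


def _markdown(sweep: SweepResult, digest: dict) -> str:
    lines = ["# Fidelity sweep summary", "",
             f"Analyzed cases: {sweep.n_analyzed}; excluded: "
             f"{len(sweep.excluded)}", "",
             "## Per fidelity (median [IQR])", "",
             "| fidelity % | duration s | accuracy % |", "|---|---|---|"]
    for row in digest["per_fidelity"]:
        lines.append(
            f"| {row['fidelity_percent']} "
            f"| {row['median_duration_s']:.2f} "
            f"[{row['duration_iqr_low']:.2f}-{row['duration_iqr_high']:.2f}] "
            f"| {row['median_accuracy_pct']:.2f} "
            f"[{row['accuracy_iqr_low']:.2f}-{row['accuracy_iqr_high']:.2f}] |")
    lines += ["", "## Paired duration contrasts", "",
              "| comparison | median diff (s) | CI | p |", "|---|---|---|---|"]
    for row in digest["adjacent_duration"]:
        lines.append(f"| {row['comparison']} | {row['median_difference']:.3f} "
                     f"| [{row['ci_low']:.3f}, {row['ci_high']:.3f}] "
                     f"({100 * row['achieved_level']:.2f}%) "
                     f"| {row['p_value']:.2e} |")
    lines += ["", "## Paired accuracy contrasts", "",
              "| comparison | median diff (%) | CI | p |", "|---|---|---|---|"]
    for row in digest["adjacent_accuracy"]:
        lines.append(f"| {row['comparison']} | {row['median_difference']:.3f} "
                     f"| [{row['ci_low']:.3f}, {row['ci_high']:.3f}] "
                     f"({100 * row['achieved_level']:.2f}%) "
                     f"| {row['p_value']:.2e} |")
    if "severity_accuracy" in digest:
        lines += ["", "## Accuracy vs reference vFFR (per fidelity)", ""]
        for row in digest["severity_accuracy"]["per_fidelity"]:
            lines.append(f"- {row['group']}%: slope {row['slope']:.2f}, "
                         f"R^2 {row['r2']:.2f}")
        lines.append(f"- slope-equality (ANCOVA) p = "
                     f"{digest['severity_accuracy']['slope_equality_p']:.2e}")
    return "\n".join(lines) + "\n"


def _figures(sweep: SweepResult, outdir: Path) -> None:
    pairs = sweep.pairs
    if len(pairs) == 0:
        return
    fids = sorted(pairs["fidelity_percent"].unique())

    fig, ax = plt.subplots(figsize=(6, 4))
    for i, p in enumerate(fids):
        d = pairs[pairs["fidelity_percent"] == p]["duration_s"]
        ax.scatter(np.full(len(d), i) + np.linspace(-0.15, 0.15, len(d)), d,
                   s=12, alpha=0.7)
        ax.hlines(np.median(d), i - 0.25, i + 0.25, color="k")
    ref_d = pairs.groupby("case_id")["duration_ref_s"].first()
    ax.scatter(np.full(len(ref_d), len(fids)) + np.linspace(-0.15, 0.15, len(ref_d)),
               ref_d, s=12, alpha=0.7)
    ax.hlines(np.median(ref_d), len(fids) - 0.25, len(fids) + 0.25, color="k")
    ax.set_xticks(range(len(fids) + 1),
                  [f"{p}%" for p in fids] + ["reference"])
    ax.set_yscale("log")
    ax.set_ylabel("simulation duration (s)")
    fig.tight_layout()
    fig.savefig(outdir / "durations.svg")
    plt.close(fig)

    fig, axes = plt.subplots(1, len(fids), figsize=(3 * len(fids), 3),
                             sharey=True)
    for ax, p in zip(np.atleast_1d(axes), fids):
        sub = pairs[pairs["fidelity_percent"] == p]
        ax.scatter(sub["mean_vffr"], sub["difference"], s=12)
        if p in sweep.bland_altman:
            ba = sweep.bland_altman[p]
            for y, ls in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
                ax.axhline(y, color="k", ls=ls, lw=0.8)
        ax.set_title(f"{p}% fidelity")
        ax.set_xlabel("mean vFFR")
    np.atleast_1d(axes)[0].set_ylabel("vFFR difference (ref - test)")
    fig.tight_layout()
    fig.savefig(outdir / "bland_altman.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for p in fids:
        sub = pairs[pairs["fidelity_percent"] == p]
        ax.scatter(sub["vffr_ref"], sub["accuracy_pct"], s=12, label=f"{p}%")
        if len(sub) >= 3:
            coef = np.polyfit(sub["vffr_ref"], sub["accuracy_pct"], 1)
            xs = np.linspace(sub["vffr_ref"].min(), sub["vffr_ref"].max(), 10)
            ax.plot(xs, np.polyval(coef, xs), lw=1)
    ax.set_xlabel("reference vFFR")
    ax.set_ylabel("accuracy (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "severity_accuracy.svg")
    plt.close(fig)
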