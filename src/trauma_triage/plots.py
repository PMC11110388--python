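"""ROC-style and age-stratified accuracy plots."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_roc_points(roc_tables, path, seed_salt: str = "0") -> None:
    """Paired sensitivity / 1-specificity points per tool, ordered by
    cumulative step depth, with observed decisions highlighted."""
    plt.rcParams["svg.hashsalt"] = seed_salt
    fig, ax = plt.subplots(figsize=(6, 5))
    for table in roc_tables:
        if table.empty:
            continue
        steps = table[table["point"] != "observed decisions"]
        obs = table[table["point"] == "observed decisions"]
        (line,) = ax.plot(steps["fpr"], steps["sensitivity"], "o-", label=str(table["tool"].iloc[0]))
        if not obs.empty:
            ax.plot(obs["fpr"], obs["sensitivity"], "*", color=line.get_color(), markersize=12)
    ax.plot([0, 1], [0, 1], ":", color="grey", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    ax.set_title("Cumulative triage-tool steps (*, observed decisions)")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def plot_age_stratified(results, path, seed_salt: str = "0") -> None:
    """Sensitivity and specificity of observed decisions by age band."""
    plt.rcParams["svg.hashsalt"] = seed_salt
    labels = [r.stratum_label for r in results]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = range(len(results))
    for name, vals, cis in (
        ("sensitivity", [r.sensitivity for r in results], [r.sensitivity_ci for r in results]),
        ("specificity", [r.specificity for r in results], [r.specificity_ci for r in results]),
    ):
        err = [[max(v - c[0], 0.0) for v, c in zip(vals, cis)],
               [max(c[1] - v, 0.0) for v, c in zip(vals, cis)]]
        ax.errorbar(x, vals, yerr=err, fmt="o-", capsize=3, label=name)
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("age band (years)")
    ax.set_ylabel("estimate (95% CI)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
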