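"""Deterministic plain-text reports for selection, profiles and traces.

Numbers are formatted at fixed precision so a re-run with the same seed
produces byte-identical reports.
"""

from __future__ import annotations

import numpy as np

from .selection import CVSummary
from .uncertainty import GainProfile


def _f(x, nd=6) -> str:
    return f"{float(x):.{nd}f}"


def format_selection_report(trace: dict, summaries: list[CVSummary]) -> str:
    lines = [
        "# threshold model selection",
        f"alpha: {_f(trace['alpha'], 4)}",
        f"common replicates: {trace['n_common_replicates']}",
        f"best by mean D2_adj: {trace['best']}",
        f"winner (most parsimonious, not significantly worse): {trace['winner']}",
        "",
        "label\tn_params\tmean_d2_adj\tsd_d2_adj\tmean_aic",
    ]
    for s in sorted(summaries, key=lambda s: s.label):
        if s.disqualified:
            lines.append(f"{s.label}\tDISQUALIFIED\t{s.disqualify_reason}")
            continue
        lines.append(
            f"{s.label}\t{s.n_params}\t{_f(s.mean_d2_adj)}"
            f"\t{_f(s.sd_d2_adj)}\t{_f(s.mean_aic, 3)}"
        )
    lines.append("")
    lines.append("pairwise tests vs best (parsimony order):")
    for t in trace["tests"]:
        lines.append(
            f"{t['label']}\tmean={_f(t['mean_d2_adj'])}"
            f"\tp={_f(t['p_vs_best'])}\tworse={t['significantly_worse']}"
        )
    return "\n".join(lines) + "\n"


def format_gain_profiles(profiles: list[GainProfile]) -> str:
    lines = ["# gain-in-explained-deviance profiles", "step\tyear\tgain_pct\tchosen"]
    for p in profiles:
        for y, g in zip(p.candidate_years, p.gain_pct):
            lines.append(
                f"{p.step}\t{int(y)}\t{_f(g)}\t{int(y) == p.chosen_year}"
            )
        lines.append(
            f"# step {p.step}: chosen {p.chosen_year}, "
            f"max gain {_f(p.max_gain_pct)} pct, "
            f"plateau width {p.plateau_width()} years"
        )
    return "\n".join(lines) + "\n"


def format_stepwise_report(trace) -> str:
    lines = [
        "# stepwise recruitment model",
        f"alpha: {_f(trace.alpha, 4)}",
        f"gain floor (pct points): {_f(trace.gain_floor_pct, 2)}",
    ]
    for step in trace.steps:
        lines.append(f"## step {step.name}")
        for c in step.candidates:
            lines.append(
                f"{c['covariate']}\tgain={_f(c['gain_pct'], 4)}"
                f"\tsd={_f(c['gain_sd_pct'], 4)}\tp={_f(c['p_value'])}"
                f"\tsignificant={c['significant']}"
            )
        lines.append(f"selected: {step.selected}")
        lines.append(f"reason: {step.stopping_reason}")
    lines.append(
        "final covariates: " + ",".join(trace.selected_covariates)
    )
    return "\n".join(lines) + "\n"
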