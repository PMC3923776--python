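"""Turnover-year importance and speed of change via gain-in-deviance profiles.

Thresholds are added greedily one at a time.  At each step, every
admissible candidate year (respecting the >= 2-year-period rule given the
thresholds already chosen) is fitted on the FULL dataset and its gain in
explained deviance over the current model is recorded, in percentage
points.  The peak gain measures a threshold's importance; the width of the
near-peak plateau measures how gradual the change was — a sharp step
concentrates the gain in one or two candidate years, a decade-long ramp
spreads it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ExhaustedCandidatesError, InvalidConfigError
from .thresholds import (
    ThresholdSpec,
    admissible_years,
    fit_threshold_model,
)


@dataclass
class GainProfile:
    """Gain in explained deviance for every candidate year at one step."""

    step: int
    base_spec: ThresholdSpec
    candidate_years: np.ndarray
    gain_pct: np.ndarray
    chosen_year: int
    base_d2_pct: float

    @property
    def max_gain_pct(self) -> float:
        return float(np.max(self.gain_pct))

    def plateau_width(self, peak_fraction: float = 0.8) -> int:
        """Span (years) of candidate years within ``peak_fraction`` of the
        peak gain — the speed-of-change summary: wide plateau, slow change."""
        near = self.candidate_years[
            self.gain_pct >= peak_fraction * self.max_gain_pct
        ]
        return int(near.max() - near.min() + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "year": self.candidate_years,
                "gain_pct": self.gain_pct,
                "chosen": self.candidate_years == self.chosen_year,
            }
        )


def _full_data_d2(records, spec, engine, degree_k, family) -> float:
    m = fit_threshold_model(records, spec, engine, degree_k, family)
    return float(m.explained_deviance)


def gain_profiles(
    records: pd.DataFrame,
    start_year: int,
    end_year: int,
    n_thresholds: int = 1,
    engine: str = "polynomial",
    degree_k: int = 2,
    family: str = "gaussian",
) -> list[GainProfile]:
    """Greedy stepwise threshold addition with a full gain profile per step.

    Step 1 profiles every admissible single turnover year against the
    no-threshold model; step s profiles adding each admissible year to the
    s-1 already chosen.  Gains are plain explained-deviance differences on
    the full data, in percentage points (n is fixed across candidates at a
    step, so the dof adjustment would only shift all gains together).
    Ties break toward the earliest year.
    """
    if n_thresholds < 1:
        raise InvalidConfigError("n_thresholds must be >= 1")
    base = ThresholdSpec(start_year, end_year)
    base_d2 = _full_data_d2(records, base, engine, degree_k, family)
    profiles: list[GainProfile] = []
    for step in range(1, n_thresholds + 1):
        years = [
            y
            for y in admissible_years(base)
            if (records["year"] < y).any() and (records["year"] >= y).any()
        ]
        if not years:
            raise ExhaustedCandidatesError(
                f"no admissible candidate year at step {step}"
            )
        gains = np.empty(len(years))
        for i, y in enumerate(years):
            d2 = _full_data_d2(
                records, base.with_year(y), engine, degree_k, family
            )
            gains[i] = 100.0 * (d2 - base_d2)
        chosen = years[int(np.argmax(gains))]
        profiles.append(
            GainProfile(
                step=step,
                base_spec=base,
                candidate_years=np.asarray(years, int),
                gain_pct=gains,
                chosen_year=int(chosen),
                base_d2_pct=100.0 * base_d2,
            )
        )
        base = base.with_year(chosen)
        base_d2 = _full_data_d2(records, base, engine, degree_k, family)
    return profiles


def rank_thresholds(
    profiles: list[GainProfile], peak_fraction: float = 0.8
) -> pd.DataFrame:
    """Thresholds ordered by importance (their step's maximum gain).

    Columns: rank, year, step, importance_gain_pct, plateau_width_years.
    """
    if not profiles:
        raise InvalidConfigError("no profiles to rank")
    rows = [
        {
            "year": p.chosen_year,
            "step": p.step,
            "importance_gain_pct": p.max_gain_pct,
            "plateau_width_years": p.plateau_width(peak_fraction),
        }
        for p in profiles
    ]
    df = (
        pd.DataFrame(rows)
        .sort_values("importance_gain_pct", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def profiles_to_frame(profiles: list[GainProfile]) -> pd.DataFrame:
    """All steps stacked in one long table (step, year, gain_pct, chosen)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def plot_gain_profiles(profiles: list[GainProfile], path=None):
    """One panel per step: gain in explained deviance per candidate year."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(profiles), 1, figsize=(7, 2.6 * len(profiles)), squeeze=False
    )
    for ax, p in zip(axes.ravel(), profiles):
        ax.bar(p.candidate_years, p.gain_pct, color="0.6")
        ax.axvline(p.chosen_year, color="k", lw=1, ls="--")
        ax.set_ylabel("gain D2 (pct pts)")
        ax.set_title(f"step {p.step}: chosen {p.chosen_year}")
    axes.ravel()[-1].set_xlabel("candidate turnover year")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
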