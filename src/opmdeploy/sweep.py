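"""Parameter sweep over the generative model: when do harmful self-fulfilling
deployments arise, and how large can the AUC increase get?

Every grid point is evaluated in closed form (no sampling), classified
for self-fulfilling status and harm, and cross-labelled with the
post-hoc audit verdict.  The output table carries the odds-ratio forms
``exp(beta_t)`` and ``exp(beta_xt)`` and the average treatment effect
as columns so the classic scatter — AUC change against treatment-effect
odds ratio, one panel per (polarity, historical rule) — can be redrawn
from the CSV alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import exp
from pathlib import Path

import numpy as np
import pandas as pd

from .audit import table1_audit, delta_sign
from .errors import AssumptionViolationError, DegenerateOPMError, InvalidParameterError
from .metrics import HarmVerdict, evaluate_scenario
from .model import OutcomeModelParams, marginal_treatment_effect
from .scenario import Polarity, ScenarioConfig

__all__ = [
    "SweepGrid",
    "run_sweep",
    "summarize_sweep",
    "write_rows",
    "read_rows",
    "validate_rows",
    "plot_sweep",
    "COLUMNS",
]

# default grid: log-odds effects spanning odds ratios ~0.14-7.4, i.e.
# moderate clinical effect sizes, without extremes
_BETA_GRID = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0)
_PX_GRID = (0.1, 0.25, 0.5, 0.75, 0.9)

#: exact column order of the sweep CSV
COLUMNS = [
    "beta0", "beta_x", "beta_t", "beta_xt", "p_x",
    "historical_policy", "polarity",
    "or_bt", "or_bxt", "avg_effect",
    "auc_pre", "auc_post", "delta_auc", "self_fulfilling",
    "harm_group0", "harm_group1", "marginal_harm",
    "calibrated_pre", "calibrated_post", "table1_verdict",
]


@dataclass(frozen=True)
class SweepGrid:
    """A Cartesian grid of generative parameters and deployment contexts."""

    beta0: tuple[float, ...] = _BETA_GRID
    beta_x: tuple[float, ...] = _BETA_GRID
    beta_t: tuple[float, ...] = _BETA_GRID
    beta_xt: tuple[float, ...] = _BETA_GRID
    p_x: tuple[float, ...] = _PX_GRID
    historical_policies: tuple[int, ...] = (0, 1)
    polarities: tuple[Polarity, ...] = (Polarity.DESIRABLE, Polarity.UNDESIRABLE)
    require_average_beneficial: bool = False

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_x", "beta_t", "beta_xt", "p_x",
                     "historical_policies", "polarities"):
            if len(getattr(self, name)) == 0:
                raise InvalidParameterError(f"grid axis {name} is empty")
        if any(not 0.0 < p < 1.0 for p in self.p_x):
            raise InvalidParameterError("p_x grid values must lie in (0, 1)")

    @property
    def n_points(self) -> int:
        return (
            len(self.beta0) * len(self.beta_x) * len(self.beta_t)
            * len(self.beta_xt) * len(self.p_x)
            * len(self.historical_policies) * len(self.polarities)
        )


def run_sweep(grid: SweepGrid | None = None) -> pd.DataFrame:
    """Evaluate every grid configuration in closed form.

    Configurations whose informed policy would be constant (the OPM
    scores both groups identically) are excluded; their count is stored
    in ``frame.attrs["n_constant_policy_excluded"]``.  When the grid
    requests only average-beneficial treatments, configurations whose
    prevalence-weighted treatment effect is not strictly positive are
    dropped too (count in ``frame.attrs["n_filtered_avg_effect"]``).
    The sweep is fully deterministic.
    """
    grid = grid or SweepGrid()
    rows: list[tuple] = []
    n_constant = 0
    n_filtered = 0
    for b0, bx, bt, bxt, px in itertools.product(
        grid.beta0, grid.beta_x, grid.beta_t, grid.beta_xt, grid.p_x
    ):
        params = OutcomeModelParams(beta0=b0, beta_x=bx, beta_t=bt, beta_xt=bxt, p_x=px)
        avg_effect = marginal_treatment_effect(params)
        for t0 in grid.historical_policies:
            if grid.require_average_beneficial and not avg_effect > 0.0:
                n_filtered += len(grid.polarities)
                continue
            try:
                # AUC and calibration are polarity-free; evaluate once
                # and relabel harm for the second polarity below.
                base = evaluate_scenario(
                    ScenarioConfig(params=params, historical_policy=t0,
                                   polarity=grid.polarities[0])
                )
            except (AssumptionViolationError, DegenerateOPMError):
                n_constant += len(grid.polarities)
                continue
            for pol in grid.polarities:
                rep = base if pol is grid.polarities[0] else evaluate_scenario(
                    ScenarioConfig(params=params, historical_policy=t0, polarity=pol)
                )
                verdict = table1_audit(pol, t0, delta_sign(rep.delta_auc, tol=1e-12))
                rows.append((
                    b0, bx, bt, bxt, px, t0, pol.value,
                    exp(bt), exp(bxt), avg_effect,
                    rep.auc_pre, rep.auc_post, rep.delta_auc, rep.self_fulfilling,
                    rep.harm_by_group[0].value, rep.harm_by_group[1].value,
                    rep.marginal_harm.value,
                    rep.calibrated_pre, rep.calibrated_post,
                    verdict.verdict.value,
                ))
    if not rows:
        import warnings

        warnings.warn("sweep produced no rows after filtering", stacklevel=2)
    frame = pd.DataFrame(rows, columns=COLUMNS)
    frame.attrs["n_constant_policy_excluded"] = n_constant
    frame.attrs["n_filtered_avg_effect"] = n_filtered
    return frame


@dataclass(frozen=True)
class SweepSummary:
    """Aggregate view of a sweep."""

    cells: pd.DataFrame  # per (polarity, historical_policy, marginal_harm)
    max_delta_auc_harmful_self_fulfilling: float
    n_harmful_self_fulfilling: int
    n_beneficial_self_defeating: int
    n_rows: int = field(default=0)


def summarize_sweep(rows: pd.DataFrame) -> SweepSummary:
    """Counts and AUC-change extrema per (polarity, historical rule, verdict).

    Also reports the headline quantities: the largest AUC increase among
    deployments that are both harmful and self-fulfilling, and the count
    of "beneficial self-defeating" deployments — those that improved
    outcomes and thereby *lowered* the AUC.
    """
    if rows.empty:
        raise InvalidParameterError("cannot summarize an empty sweep")
    cells = (
        rows.groupby(["polarity", "historical_policy", "marginal_harm"])
        .agg(
            n=("delta_auc", "size"),
            delta_auc_min=("delta_auc", "min"),
            delta_auc_max=("delta_auc", "max"),
        )
        .reset_index()
    )
    harmful_sf = rows[
        (rows["marginal_harm"] == HarmVerdict.HARMFUL.value) & rows["self_fulfilling"]
    ]
    beneficial_sd = rows[
        (rows["marginal_harm"] == HarmVerdict.BENEFICIAL.value)
        & (rows["delta_auc"] < 0)
    ]
    return SweepSummary(
        cells=cells,
        max_delta_auc_harmful_self_fulfilling=(
            float(harmful_sf["delta_auc"].max()) if len(harmful_sf) else float("nan")
        ),
        n_harmful_self_fulfilling=int(len(harmful_sf)),
        n_beneficial_self_defeating=int(len(beneficial_sd)),
        n_rows=int(len(rows)),
    )


def write_rows(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the sweep table as CSV (deterministic for identical grids)."""
    rows.to_csv(path, index=False)


def read_rows(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a sweep CSV back; optionally re-validate every row."""
    frame = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidParameterError(f"sweep CSV missing columns: {missing}")
    if validate:
        validate_rows(frame)
    return frame


def validate_rows(rows: pd.DataFrame, atol: float = 1e-9) -> None:
    """Recompute every row's deployment report and check self-consistency.

    Raises
    ------
    InvalidParameterError
        On the first row whose stored metrics disagree with a fresh
        closed-form evaluation.
    """
    for idx, row in rows.iterrows():
        scenario = ScenarioConfig(
            params=OutcomeModelParams(
                beta0=row["beta0"], beta_x=row["beta_x"], beta_t=row["beta_t"],
                beta_xt=row["beta_xt"], p_x=row["p_x"],
            ),
            historical_policy=int(row["historical_policy"]),
            polarity=Polarity(row["polarity"]),
        )
        rep = evaluate_scenario(scenario)
        ok = (
            np.isclose(rep.auc_pre, row["auc_pre"], atol=atol)
            and np.isclose(rep.auc_post, row["auc_post"], atol=atol)
            and rep.marginal_harm.value == row["marginal_harm"]
            and bool(rep.self_fulfilling) == bool(row["self_fulfilling"])
        )
        if not ok:
            raise InvalidParameterError(f"row {idx} fails re-validation: {dict(row)}")


def plot_sweep(rows: pd.DataFrame, path: str | Path) -> None:
    """Four-panel scatter of AUC change vs. treatment-effect odds ratio.

    One panel per (polarity, historical rule); points coloured by the
    interaction odds ratio.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8), sharex=True, sharey=True)
    panels = [
        (Polarity.DESIRABLE.value, 1), (Polarity.DESIRABLE.value, 0),
        (Polarity.UNDESIRABLE.value, 1), (Polarity.UNDESIRABLE.value, 0),
    ]
    for ax, (pol, t0) in zip(axes.ravel(), panels):
        sub = rows[(rows["polarity"] == pol) & (rows["historical_policy"] == t0)]
        sc = ax.scatter(sub["or_bt"], sub["delta_auc"], c=sub["or_bxt"],
                        s=6, cmap="viridis", norm=matplotlib.colors.LogNorm())
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xscale("log")
        rule = "treat everyone" if t0 == 1 else "treat no one"
        ax.set_title(f"Y=1 {pol}, historically {rule}", fontsize=10)
    fig.supxlabel("treatment effect, odds ratio $e^{\\beta_t}$")
    fig.supylabel("AUC(post) $-$ AUC(pre)")
    fig.colorbar(sc, ax=axes, label="interaction odds ratio $e^{\\beta_{xt}}$")
    fig.savefig(path, dpi=150)
    plt.close(fig)
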