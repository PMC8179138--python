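"""Free energy perturbation: Zwanzig windows, leg accumulation, cycle closure.

A relative binding free energy is computed from two alchemical "legs" — the
transformation of ligand A into ligand B in the receptor-bound state and in
aqueous solution — combined through the thermodynamic cycle

    ddG_bind = dG_transform(bound) - dG_transform(unbound).

Each leg is a ladder of lambda windows; the free energy of each window is
estimated from samples at the lower lambda with the Zwanzig (exponential
averaging) formula

    dF_i = -kT * ln < exp(-(U_{i+1} - U_i) / kT) >_i .
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import K_B
from ._stats import block_apply_sem

log = logging.getLogger(__name__)

#: Fraction of frames inspected by the overlap diagnostic.
_TOP_FRAME_FRACTION = 0.05
#: Warn when more than this share of the exponential-average weight is
#: carried by the top 5% of frames.
_OVERLAP_WARN_THRESHOLD = 0.5


@dataclass(frozen=True)
class LambdaLadder:
    """Ordered alchemical coupling values from 0 (state A) to 1 (state B)."""

    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        lams = tuple(float(x) for x in self.lambdas)
        if len(lams) < 2:
            raise ValueError("ladder needs at least 2 lambda values")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise ValueError("ladder must start at 0 and end at 1")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambdas must be strictly increasing")
        object.__setattr__(self, "lambdas", lams)

    @classmethod
    def evenly_spaced(cls, n_windows: int = 84) -> "LambdaLadder":
        """Ladder of ``n_windows`` equal intervals (n_windows + 1 states)."""
        if n_windows < 1:
            raise ValueError("need at least one window")
        return cls(tuple(np.linspace(0.0, 1.0, n_windows + 1)))

    @property
    def n_windows(self) -> int:
        return len(self.lambdas) - 1

    def reversed(self) -> "LambdaLadder":
        """The ladder of the reverse transformation (B -> A)."""
        return LambdaLadder(tuple(1.0 - x for x in reversed(self.lambdas)))


@dataclass
class PerturbationSeries:
    """Per-frame energy differences between adjacent lambda states.

    ``delta_u`` holds U_{lambda_{i+1}} - U_{lambda_i} (kcal/mol) evaluated on
    frames sampled at lambda_i, after equilibration has been discarded.
    """

    window_index: int
    lam: float
    delta_u: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.delta_u = np.asarray(self.delta_u, dtype=float)
        if self.delta_u.size == 0:
            raise ValueError("empty perturbation series")
        if not np.all(np.isfinite(self.delta_u)):
            raise ValueError("non-finite delta_U in perturbation series")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda outside [0, 1]")
        if self.temperature <= 0:
            raise ValueError("non-positive temperature")


@dataclass(frozen=True)
class WindowEstimate:
    """Zwanzig estimate for one lambda window."""

    window_index: int
    lam: float
    delta_f: float
    sem: float
    n_frames: int
    #: share of the exponential-average weight carried by the top 5% of frames
    top_weight_fraction: float
    temperature: float


@dataclass
class FreeEnergyResult:
    """Accumulated free energy of one alchemical leg."""

    leg_label: str
    window_dgs: np.ndarray
    leg_dg: float
    leg_sem: float
    temperature: float
    replicate_dgs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.window_dgs = np.asarray(self.window_dgs, dtype=float)
        if abs(self.leg_dg - self.window_dgs.sum()) > 1e-9 and not self.replicate_dgs:
            raise ValueError("leg_dg must equal the window sum")
        if self.leg_sem < 0:
            raise ValueError("negative SEM")


@dataclass
class RelativeBindingFreeEnergy:
    """ddG_bind from the thermodynamic cycle, with replicate statistics."""

    ddg: float
    sem: float
    bound: FreeEnergyResult
    unbound: FreeEnergyResult
    replicate_ddgs: list[float] = field(default_factory=list)

    @property
    def temperature(self) -> float:
        return self.bound.temperature


def _zwanzig_point(delta_u: np.ndarray, kt: float) -> float:
    n = delta_u.size
    return float(-kt * (logsumexp(-delta_u / kt) - np.log(n)))


def zwanzig_window(series: PerturbationSeries, n_blocks: int = 10) -> WindowEstimate:
    """Free energy of one window by exponential averaging.

    dF = -kT ln<exp(-dU/kT)> via a numerically stable log-sum-exp; the SEM
    comes from block averaging (default 10 contiguous blocks).  The overlap
    diagnostic reports the fraction of the total Boltzmann weight carried by
    the top 5% of frames; a warning is logged when it exceeds 50%.
    """
    du = series.delta_u
    if du.size < 10:
        warnings.warn(
            f"window {series.window_index}: only {du.size} retained frames",
            stacklevel=2,
        )
    kt = K_B * series.temperature
    delta_f = _zwanzig_point(du, kt)

    # overlap diagnostic: normalized weights of exp(-dU/kT)
    logw = -du / kt
    logw -= logsumexp(logw)
    w = np.exp(logw)
    n_top = max(1, int(np.ceil(_TOP_FRAME_FRACTION * du.size)))
    top_weight = float(np.sort(w)[::-1][:n_top].sum())
    if top_weight > _OVERLAP_WARN_THRESHOLD:
        log.warning(
            "window %d (lambda=%.4f): %.0f%% of the exponential-average weight "
            "comes from the top %d frames — poor phase-space overlap",
            series.window_index,
            series.lam,
            100 * top_weight,
            n_top,
        )

    if np.ptp(du) == 0.0:
        sem = 0.0  # degenerate distribution: the estimate is exact
    else:
        sem = block_apply_sem(du, lambda b: _zwanzig_point(b, kt), n_blocks)
    return WindowEstimate(
        window_index=series.window_index,
        lam=series.lam,
        delta_f=delta_f,
        sem=sem,
        n_frames=du.size,
        top_weight_fraction=top_weight,
        temperature=series.temperature,
    )


def accumulate_leg(
    windows: Sequence[WindowEstimate],
    label: str,
    ladder: LambdaLadder | None = None,
) -> FreeEnergyResult:
    """Sum window free energies along the lambda path into a leg dG.

    Windows must be ordered by lambda.  Window SEMs combine in quadrature
    (windows are sampled independently).
    """
    if not windows:
        raise ValueError("no windows to accumulate")
    if ladder is not None and len(windows) != ladder.n_windows:
        raise ValueError(
            f"window count {len(windows)} does not match ladder "
            f"({ladder.n_windows} windows)"
        )
    lams = [w.lam for w in windows]
    if any(b < a for a, b in zip(lams, lams[1:])):
        raise ValueError("windows must be ordered by lambda")
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise ValueError("windows at mixed temperatures")
    dgs = np.array([w.delta_f for w in windows])
    sem = float(np.sqrt(np.sum([w.sem**2 for w in windows])))
    dg = float(dgs.sum())
    return FreeEnergyResult(
        leg_label=label,
        window_dgs=dgs,
        leg_dg=dg,
        leg_sem=sem,
        temperature=temps.pop(),
        replicate_dgs=[dg],
    )


def pool_replicates(results: Sequence[FreeEnergyResult]) -> FreeEnergyResult:
    """Aggregate independent-seed replicate legs into mean +/- SEM."""
    if not results:
        raise ValueError("no replicates")
    labels = {r.leg_label for r in results}
    temps = {r.temperature for r in results}
    if len(labels) != 1 or len(temps) != 1:
        raise ValueError("replicates must share leg label and temperature")
    reps = [dg for r in results for dg in r.replicate_dgs]
    mean = float(np.mean(reps))
    sem = float(np.std(reps, ddof=1) / np.sqrt(len(reps))) if len(reps) > 1 else 0.0
    window_dgs = np.mean([r.window_dgs for r in results], axis=0)
    return FreeEnergyResult(
        leg_label=labels.pop(),
        window_dgs=window_dgs,
        leg_dg=mean,
        leg_sem=sem,
        temperature=temps.pop(),
        replicate_dgs=reps,
    )


def cycle_combine(
    bound: FreeEnergyResult, unbound: FreeEnergyResult
) -> RelativeBindingFreeEnergy:
    """Close the thermodynamic cycle: ddG = dG_bound - dG_unbound.

    When both legs carry the same number of replicates, ddG is the mean of
    the per-replicate differences and the SEM is computed over those
    differences; otherwise the leg SEMs combine in quadrature.
    """
    if bound.temperature != unbound.temperature:
        raise ValueError(
            f"temperature mismatch: bound at {bound.temperature} K, "
            f"unbound at {unbound.temperature} K"
        )
    replicate_ddgs: list[float] = []
    nb, nu = len(bound.replicate_dgs), len(unbound.replicate_dgs)
    if nb == nu and nb > 1:
        replicate_ddgs = [
            b - u for b, u in zip(bound.replicate_dgs, unbound.replicate_dgs)
        ]
        ddg = float(np.mean(replicate_ddgs))
        sem = float(np.std(replicate_ddgs, ddof=1) / np.sqrt(nb))
    else:
        ddg = bound.leg_dg - unbound.leg_dg
        sem = float(np.hypot(bound.leg_sem, unbound.leg_sem))
    return RelativeBindingFreeEnergy(
        ddg=ddg, sem=sem, bound=bound, unbound=unbound, replicate_ddgs=replicate_ddgs
    )


def estimate_leg(
    series_list: Sequence[PerturbationSeries],
    label: str,
    ladder: LambdaLadder | None = None,
) -> FreeEnergyResult:
    """Convenience: Zwanzig on every window then accumulate into a leg."""
    windows = [zwanzig_window(s) for s in series_list]
    return accumulate_leg(windows, label, ladder)
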