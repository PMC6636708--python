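"""Forward-in-time birth-death simulation of dated trees.

Generates synthetic dated phylogenies under constant, time-varying
(exponential) and density-dependent speciation, with constant extinction.
Simulation is event-driven and exact: between events the total rate is
constant (or, in the time-varying mode, bounded and thinned against a
dominating constant rate), so waiting times are drawn from the true
distribution.  A fixed seed yields a bit-identical event log.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .rates import FamilyRecord
from .tree_io import DatedTree, Node, prune_to_extant

__all__ = [
    "BDParams",
    "SimResult",
    "SurvivalConditioningError",
    "simulate_tree",
    "simulate_family_table",
    "expected_n",
]

Mode = Literal["constant", "exponential_time", "density_dependent"]


class SurvivalConditioningError(RuntimeError):
    """Raised when conditioning on survival exceeds the retry cap."""


@dataclass(frozen=True)
class BDParams:
    """Generative parameters for the birth-death simulator.

    ``lambda0`` and ``mu0`` are the per-lineage speciation and extinction
    rates in yr^-1.  The speciation rate may vary with elapsed time
    (``exponential_time``: lambda(t) = lambda0 * exp(beta * t)) or with the
    standing diversity (``density_dependent``: lambda(N) = lambda0 *
    max(0, 1 - N/K)).  Exactly one stopping rule (``max_time`` in years or
    ``max_tips``) must be set.
    """

    lambda0: float
    mu0: float = 0.0
    mode: Mode = "constant"
    beta: float | None = None
    K: float | None = None
    max_time: float | None = None
    max_tips: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.mu0 < 0:
            raise ValueError("mu0 must be non-negative")
        if self.mode not in ("constant", "exponential_time", "density_dependent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "exponential_time" and self.beta is None:
            raise ValueError("exponential_time mode requires beta")
        if self.mode == "density_dependent":
            if self.K is None or self.K < 2:
                raise ValueError("density_dependent mode requires K >= 2")
        if (self.max_time is None) == (self.max_tips is None):
            raise ValueError("exactly one of max_time / max_tips must be set")
        if self.max_time is not None and self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.max_tips is not None and self.max_tips < 2:
            raise ValueError("max_tips must be >= 2")

    def speciation_rate(self, t: float, n: int) -> float:
        if self.mode == "constant":
            return self.lambda0
        if self.mode == "exponential_time":
            return self.lambda0 * math.exp(self.beta * t)
        return self.lambda0 * max(0.0, 1.0 - n / self.K)


@dataclass(frozen=True)
class SimResult:
    """Outcome of one simulation.

    ``tree`` is the crown tree of the surviving lineages (extinct branches
    pruned); it is None when no lineage survived.  ``event_log`` records
    (elapsed time, "birth" | "death", lineage id) in order; replaying it
    reconstructs the lineage count at every step.  ``stem_age`` is the total
    elapsed simulation time, measured from the single founding lineage.
    """

    tree: DatedTree | None
    event_log: list[tuple[float, str, int]]
    params: BDParams
    n_extant: int
    stem_age: float
    n_attempts: int = 1


def _attempt(params: BDParams, rng: np.random.Generator):
    """One unconditioned forward simulation."""
    horizon = params.max_time if params.max_time is not None else math.inf
    t = 0.0
    next_id = 1
    # open segment per live lineage: lineage id -> (Node, segment start time)
    root_seg = Node()
    open_segs: dict[int, tuple[Node, float]] = {0: (root_seg, 0.0)}
    log: list[tuple[float, str, int]] = []

    # window over which the dominating rate is valid (time-varying mode only)
    if params.mode == "exponential_time" and params.beta and params.beta > 0:
        window = 1.0 / params.beta  # rate grows by at most a factor e per window
    else:
        window = math.inf

    iterations = 0
    while open_segs:
        iterations += 1
        if iterations > 50_000_000:  # stalled thinning loop (vanishing rates, no horizon)
            raise RuntimeError("simulation failed to terminate; check rate parameters")
        n = len(open_segs)
        if params.max_tips is not None and n >= params.max_tips:
            break
        window_end = min(t + window, horizon)
        lam_now = params.speciation_rate(t, n)
        lam_up = max(lam_now, params.speciation_rate(window_end, n)) if window_end < math.inf else lam_now
        total_up = n * (lam_up + params.mu0)
        if total_up <= 0.0:
            # rates extinguished (e.g. at carrying capacity with mu0 = 0)
            if horizon == math.inf:
                raise RuntimeError("event rate fell to zero with no time horizon; simulation cannot finish")
            t = horizon
            break
        gap = rng.exponential(1.0 / total_up)
        if t + gap >= window_end:
            t = window_end
            if t >= horizon:
                break
            continue  # advance the thinning window, no event
        t = t + gap
        lam_t = params.speciation_rate(t, n)
        # thinning: accept with prob (true rate / dominating rate)
        if rng.random() * total_up >= n * (lam_t + params.mu0):
            continue
        lineage = list(open_segs)[rng.integers(n)]
        is_birth = rng.random() * (lam_t + params.mu0) < lam_t
        seg, t0 = open_segs.pop(lineage)
        seg.length = t - t0
        if is_birth:
            child_a, child_b = Node(), Node()
            seg.children = [child_a, child_b]
            open_segs[lineage] = (child_a, t)
            open_segs[next_id] = (child_b, t)
            log.append((t, "birth", next_id))
            next_id += 1
        else:
            seg.label = f"t{lineage}"
            log.append((t, "death", lineage))

    # close surviving segments as extant tips at the stop time
    for lineage, (seg, t0) in open_segs.items():
        seg.length = t - t0
        seg.label = f"t{lineage}"
    return root_seg, len(open_segs), t, log


def _as_tree(root_seg: Node, n_extant: int, family_name: str | None) -> DatedTree | None:
    """Full tree (extinct tips included) -> crown tree of survivors."""
    if n_extant == 0:
        return None
    if not root_seg.children:
        # the founder never branched: a degenerate single-tip tree whose
        # root-to-tip span is the full elapsed time
        return DatedTree(Node(children=[root_seg]), family_name=family_name)
    root_seg.length = None  # drop the stem edge; stem_age is reported separately
    full = DatedTree(root_seg, family_name=family_name)
    if n_extant == full.n_tips:
        return full
    return prune_to_extant(full)


def simulate_tree(
    params: BDParams,
    condition_on_survival: bool = True,
    min_tips: int = 2,
    max_retries: int = 10_000,
    rng: np.random.Generator | None = None,
    family_name: str | None = None,
) -> SimResult:
    """Simulate one dated tree.

    By default the simulation is conditioned, by rejection, on at least
    ``min_tips`` extant lineages at the stopping point; the retry cap guards
    against parameter regimes where survival is too rare.  Pass
    ``condition_on_survival=False`` for unconditioned draws (used by the
    moment tests); the tree is then None whenever nothing survives.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    attempts = 0
    while True:
        attempts += 1
        root_seg, n_extant, elapsed, log = _attempt(params, rng)
        if not condition_on_survival or n_extant >= min_tips:
            tree = _as_tree(root_seg, n_extant, family_name)
            return SimResult(tree, log, params, n_extant, elapsed, attempts)
        if attempts >= max_retries:
            raise SurvivalConditioningError(
                f"no replicate reached {min_tips} surviving lineages in "
                f"{max_retries} attempts (estimated survival probability "
                f"< {1.0 / max_retries:.2e})"
            )


def simulate_family_table(
    n_families: int,
    root_age_range: tuple[float, float] = (1000.0, 8700.0),
    size_model: BDParams | None = None,
    seed: int | None = None,
) -> tuple[list[FamilyRecord], list[SimResult]]:
    """Simulate a synthetic family summary table plus its trees.

    Root ages (simulation horizons) are drawn uniformly from
    ``root_age_range``; one conditioned tree is simulated per family, and the
    family record's catalog counts are both set to the extant tip count.  The
    recorded root age is the crown age of the simulated tree.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    lo, hi = root_age_range
    if not (0 < lo <= hi):
        raise ValueError("invalid root_age_range")
    if size_model is None:
        size_model = BDParams(lambda0=0.001, mu0=0.0, max_time=lo)
    rng = np.random.default_rng(seed)
    records, results = [], []
    for i in range(n_families):
        horizon = rng.uniform(lo, hi)
        params = dataclasses.replace(size_model, max_time=horizon, max_tips=None, seed=None)
        name = f"sim{i:03d}"
        res = simulate_tree(params, rng=rng, family_name=name)
        assert res.tree is not None
        records.append(
            FamilyRecord(
                family=name,
                root_age=res.tree.root_age,
                n_sample=res.n_extant,
                n_ethnologue=res.n_extant,
                n_glottolog=res.n_extant,
                source="simulated",
            )
        )
        results.append(res)
    return records, results


def expected_n(params: BDParams, t: float) -> float:
    """Expected lineage count e^{(lambda - mu) t} from one founder.

    Only defined for the constant-rates mode (no closed form is provided for
    the other modes).
    """
    if params.mode != "constant":
        raise ValueError("expected_n has a closed form only in constant mode")
    return math.exp((params.lambda0 - params.mu0) * t)
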