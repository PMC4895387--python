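"""Metropolis-Hastings sampling of the genome-wide membership vector.

The chain state is the label vector ``I`` in ``{0,1,2}^L``.  Two proposal
kernels are mixed:

* **relabel** — pick a non-empty group uniformly, a locus uniformly inside
  it, and one of the two alternative labels uniformly;
* **exchange** — pick an unordered pair of distinct non-empty groups
  uniformly, one locus uniformly from each, and swap their labels.

When fewer than two groups are non-empty a relabel move is forced.  The exact
Hastings transition ratio under these selection rules is returned with each
proposal; for an exchange move forward and reverse selection probabilities
coincide, so the log ratio is zero.

Because the locus marginal factors are cached, a proposal is evaluated from
two (relabel) or four (exchange) cache lookups plus the change in the
Dirichlet-multinomial prior term — the only term coupling loci.

Reproducibility: one named NumPy generator drives the chain.  The draw order
per proposal is fixed: move-type uniform, group index draw(s), locus
draw(s), target-label draw (relabel only), acceptance uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .model import compute_log_marginals
from .types import Hyperparameters, LocusCounts

__all__ = [
    "ChainConfig",
    "PartitionState",
    "ProposalMove",
    "PosteriorSummary",
    "propose_move",
    "apply_move",
    "acceptance_probability",
    "run_chain",
    "classify_loci",
]


@dataclass
class ChainConfig:
    """Sampler settings.

    A *sweep* is ``L`` single-move proposals; one membership snapshot is
    recorded per post-burn-in sweep.  Defaults: 2000 sweeps, half discarded
    as burn-in, random-uniform initial labels.
    """

    n_sweeps: int = 2000
    burn_in_fraction: float = 0.5
    seed: int = 0
    init_mode: str = "random-uniform"  # or "all-equal", "user"
    init_labels: np.ndarray | None = None
    exchange_prob: float = 0.5
    trace: bool = False

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be positive")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_sweeps - int(self.n_sweeps * self.burn_in_fraction) < 1:
            raise ValueError("post-burn-in sample count must be at least 1")
        if not (0.0 <= self.exchange_prob <= 1.0):
            raise ValueError("exchange_prob must be in [0, 1]")
        if self.init_mode not in ("random-uniform", "all-equal", "user"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "user" and self.init_labels is None:
            raise ValueError("init_mode='user' requires init_labels")

    @property
    def n_burn_in(self) -> int:
        return int(self.n_sweeps * self.burn_in_fraction)


class PartitionState:
    """Membership vector with per-group member lists for O(1) uniform draws."""

    __slots__ = ("membership", "members", "position")

    def __init__(self, membership) -> None:
        self.membership = np.asarray(membership, dtype=np.int64).copy()
        if self.membership.ndim != 1 or self.membership.size == 0:
            raise ValueError("membership must be a non-empty vector")
        if self.membership.min() < 0 or self.membership.max() > 2:
            raise ValueError("labels must be in {0, 1, 2}")
        self.members: list[list[int]] = [[], [], []]
        self.position = np.empty(self.membership.size, dtype=np.int64)
        for i, g in enumerate(self.membership):
            self.position[i] = len(self.members[g])
            self.members[int(g)].append(i)

    @property
    def group_counts(self) -> tuple[int, int, int]:
        return (len(self.members[0]), len(self.members[1]), len(self.members[2]))

    def relabel(self, locus: int, new_label: int) -> None:
        old = int(self.membership[locus])
        grp = self.members[old]
        pos = int(self.position[locus])
        last = grp[-1]
        grp[pos] = last
        self.position[last] = pos
        grp.pop()
        self.position[locus] = len(self.members[new_label])
        self.members[new_label].append(locus)
        self.membership[locus] = new_label


@dataclass(frozen=True)
class ProposalMove:
    kind: str  # "relabel" or "exchange"
    loci: tuple[int, ...]
    old_labels: tuple[int, ...]
    new_labels: tuple[int, ...]
    log_transition_ratio: float


def propose_move(
    state: PartitionState, rng: np.random.Generator, exchange_prob: float = 0.5
) -> ProposalMove:
    """Draw one proposal from the mixed kernel with its exact Hastings ratio."""
    counts = state.group_counts
    nonempty = [j for j in range(3) if counts[j] > 0]
    n_groups = len(nonempty)
    if state.membership.size == 0:
        raise ValueError("cannot propose on an empty state")
    u = rng.random()  # move-type draw happens unconditionally (fixed stream)
    if n_groups >= 2 and u < exchange_prob:
        # exchange: unordered pair of distinct non-empty groups, then a locus
        # from each; group sizes and the non-empty set are unchanged by the
        # swap, so forward and reverse selection probabilities coincide.
        pairs = [(a, b) for ia, a in enumerate(nonempty) for b in nonempty[ia + 1:]]
        g1, g2 = pairs[int(rng.integers(len(pairs)))]
        i = state.members[g1][int(rng.integers(counts[g1]))]
        j = state.members[g2][int(rng.integers(counts[g2]))]
        return ProposalMove(
            kind="exchange",
            loci=(i, j),
            old_labels=(g1, g2),
            new_labels=(g2, g1),
            log_transition_ratio=0.0,
        )
    # relabel (forced when fewer than two groups are occupied)
    relabel_prob_fwd = 1.0 if n_groups < 2 else (1.0 - exchange_prob)
    g = nonempty[int(rng.integers(n_groups))]
    i = state.members[g][int(rng.integers(counts[g]))]
    alts = [t for t in range(3) if t != g]
    t = alts[int(rng.integers(2))]
    new_counts = list(counts)
    new_counts[g] -= 1
    new_counts[t] += 1
    n_groups_new = sum(1 for c in new_counts if c > 0)
    relabel_prob_rev = 1.0 if n_groups_new < 2 else (1.0 - exchange_prob)
    log_fwd = (
        math.log(relabel_prob_fwd)
        - math.log(n_groups)
        - math.log(counts[g])
        - math.log(2.0)
    )
    log_rev = (
        math.log(relabel_prob_rev)
        - math.log(n_groups_new)
        - math.log(new_counts[t])
        - math.log(2.0)
    )
    return ProposalMove(
        kind="relabel",
        loci=(i,),
        old_labels=(g,),
        new_labels=(t,),
        log_transition_ratio=log_rev - log_fwd,
    )


def apply_move(state: PartitionState, move: ProposalMove) -> None:
    """Mutate ``state`` by applying an accepted move."""
    if move.kind == "relabel":
        state.relabel(move.loci[0], move.new_labels[0])
    elif move.kind == "exchange":
        i, j = move.loci
        g1, g2 = move.old_labels
        state.relabel(i, g2)
        state.relabel(j, g1)
    else:  # pragma: no cover
        raise ValueError(f"unknown move kind {move.kind!r}")


def acceptance_probability(
    log_post_new: float, log_post_old: float, log_transition_ratio: float = 0.0
) -> float:
    """Metropolis-Hastings acceptance probability ``min{1, r}`` in log form."""
    args = (log_post_new, log_post_old, log_transition_ratio)
    if any(math.isnan(v) for v in args):
        raise ValueError("NaN in acceptance probability inputs")
    delta = log_post_new - log_post_old + log_transition_ratio
    if delta >= 0.0:
        return 1.0
    return math.exp(delta)


@dataclass
class PosteriorSummary:
    """Post-burn-in membership summary.

    ``membership_counts[i, j]`` is the number of recorded sweeps in which
    locus ``i`` carried label ``j``; probabilities are these frequencies over
    the common denominator ``n_samples_used``.
    """

    membership_probability: np.ndarray
    membership_counts: np.ndarray
    call: np.ndarray
    acceptance_rate: float
    n_samples_used: int
    trace: np.ndarray | None = None


def classify_loci(summary_or_counts) -> np.ndarray:
    """Highest-posterior-probability call per locus with conservative ties.

    An exact tie involving group 0, or a tie between groups 1 and 2, resolves
    to group 0: no directional claim without a strict winner.
    """
    counts = (
        summary_or_counts.membership_counts
        if isinstance(summary_or_counts, PosteriorSummary)
        else np.asarray(summary_or_counts)
    )
    counts = np.atleast_2d(counts)
    calls = np.empty(counts.shape[0], dtype=np.int64)
    for i, row in enumerate(counts):
        mx = row.max()
        if row[0] == mx:
            calls[i] = 0
        elif row[1] == mx and row[2] == mx:
            calls[i] = 0
        else:
            calls[i] = int(np.argmax(row))
    return calls


def run_chain(
    data: list[LocusCounts] | None,
    hyper: Hyperparameters | None = None,
    config: ChainConfig | None = None,
    log_g: np.ndarray | None = None,
) -> PosteriorSummary:
    """Sample the membership posterior and summarize it.

    Identical ``data``, ``hyper`` and ``config`` (including seed) give
    bit-identical output.  ``log_g`` may pass a precomputed marginal cache.
    """
    hyper = hyper or Hyperparameters()
    config = config or ChainConfig()
    if log_g is None:
        if not data:
            raise ValueError("data must be non-empty")
        log_g = compute_log_marginals(data, hyper)
    L = log_g.shape[0]
    rng = np.random.default_rng(config.seed)

    if config.init_mode == "random-uniform":
        init = rng.integers(0, 3, size=L)
    elif config.init_mode == "all-equal":
        init = np.zeros(L, dtype=np.int64)
    else:
        init = np.asarray(config.init_labels, dtype=np.int64)
        if init.shape != (L,):
            raise ValueError("init_labels length must match data")
    state = PartitionState(init)

    # Only Gamma(k_j + l_j) terms of the partition prior change with a move
    # (the total L is fixed), so cache log-gamma over all reachable counts.
    k = hyper.dirichlet
    lgam = [special.gammaln(k[j] + np.arange(L + 2)) for j in range(3)]

    counters = np.zeros((L, 3), dtype=np.int64)
    n_burn = config.n_burn_in
    n_rec = config.n_sweeps - n_burn
    trace = np.empty((n_rec, L), dtype=np.int8) if config.trace else None
    accepted = 0
    total = config.n_sweeps * L
    membership = state.membership
    exchange_prob = config.exchange_prob

    for sweep in range(config.n_sweeps):
        for _ in range(L):
            move = propose_move(state, rng, exchange_prob)
            if move.kind == "relabel":
                i = move.loci[0]
                g, t = move.old_labels[0], move.new_labels[0]
                lg, lt = len(state.members[g]), len(state.members[t])
                delta = (
                    log_g[i, t]
                    - log_g[i, g]
                    + lgam[g][lg - 1]
                    - lgam[g][lg]
                    + lgam[t][lt + 1]
                    - lgam[t][lt]
                )
            else:
                i, j = move.loci
                g1, g2 = move.old_labels
                delta = (
                    log_g[i, g2] - log_g[i, g1] + log_g[j, g1] - log_g[j, g2]
                )
            log_alpha = delta + move.log_transition_ratio
            u_acc = rng.random()  # drawn unconditionally: fixed stream order
            if log_alpha >= 0.0 or u_acc < math.exp(log_alpha):
                apply_move(state, move)
                accepted += 1
        if sweep >= n_burn:
            counters[np.arange(L), membership] += 1
            if trace is not None:
                trace[sweep - n_burn] = membership

    probs = counters / float(n_rec)
    return PosteriorSummary(
        membership_probability=probs,
        membership_counts=counters,
        call=classify_loci(counters),
        acceptance_rate=accepted / total,
        n_samples_used=n_rec,
        trace=trace,
    )
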