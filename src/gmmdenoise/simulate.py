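"""Simulation of eDNA metabarcoding: PCR with substitution artefacts, then sequencing.

The model tracks a pool of unique amplicon sequences through repeated PCR
cycles.  A template pool of ``n_true`` random reference variants receives
initial proportional abundances from a symmetric Dirichlet; each cycle every
sequence gains new copies in proportion to its abundance, a sequence-specific
amplification efficiency drawn from a Beta distribution, and a small lognormal
stochastic factor.  A per-cycle substitution rate (Beta-distributed, matching
published error-rate estimates for a high-fidelity polymerase) converts a
fraction of the newly created copies into single-substitution artefacts at a
uniformly random position; only transitions (A<->G, C<->T) are introduced.
Artefacts inherit the amplification efficiency of their template, join the
pool, and can themselves be amplified and mutated in later cycles.  The pool
is dereplicated every cycle, so identical mutations and reverse mutations
merge.  Sequencing is a single multinomial draw of ``n_seq_reads`` reads over
the final proportional abundances.

Two parallel bookkeepings are maintained, following the model's structure:
proportional abundances ``a`` drive the composition that is ultimately
sequenced, while absolute copy numbers ``A`` discretise the occurrence of
artefacts (an artefact count must be an integer, hence the floors).  Absolute
copy numbers grow un-normalised — each molecule is duplicated at rate
``p*eps`` per cycle — which is the reading of the absolute-abundance
recursion that reproduces the intended artefact load; two alternative
readings are available through ``SimConfig.growth`` for comparison (see
``docs/methods.md``).

Sequences are represented structurally as (reference index, set of positions
carrying an odd number of transitions): transitions are involutions, so this
keying makes dereplication (including reverse mutations) exact without
materialising strings until output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import ASVTable

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "SummaryStats",
    "ReplicateSummary",
    "make_reference_pool",
    "draw_efficiencies",
    "pcr_cycle",
    "run_pcr",
    "sequence_amplicons",
    "simulate",
    "run_replicates",
    "density_summary",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated eDNA metabarcoding run.

    Defaults are the study conditions: 100 true 160-bp variants at 56% GC,
    Dirichlet(1) initial proportions over a 10,000-read extract, Beta(5,5)
    amplification efficiencies (mean 0.5, SD 0.15), Lognormal(0, 0.05^2)
    per-cycle noise, Beta(36, 3e6) substitution rate (mean 1.2e-5), 35 PCR
    cycles and 1.5e6 sequencing reads.
    """

    n_true: int = 100
    seq_len: int = 160
    gc: float = 0.56
    gamma: float = 1.0
    eff_alpha: float = 5.0
    eff_beta: float = 5.0
    err_alpha: float = 36.0
    err_beta: float = 3e6
    eps_mu: float = 0.0
    eps_sigma: float = 0.05
    n_cycles: int = 35
    pool_reads: int = 10_000
    n_seq_reads: int = 1_500_000
    seed: int | None = None
    # model-reading switches (see module docstring); defaults are the
    # validated reading, alternatives are kept for comparison.
    growth: str = "exponential"  # "exponential" | "competitive" | "literal"
    eps_per_sequence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.growth not in ("exponential", "competitive", "literal"):
            raise ValueError(f"unknown growth mode {self.growth!r}")
        for name in ("gamma", "eff_alpha", "eff_beta", "err_alpha", "err_beta", "eps_sigma"):
            if getattr(self, name) <= 0 and name != "eps_sigma":
                raise ValueError(f"{name} must be > 0")
        if self.n_true < 1 or self.seq_len < 1 or self.pool_reads < 1 or self.n_seq_reads < 1:
            raise ValueError("sizes must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimState:
    """Evolving amplicon pool.

    ``roots`` holds the reference nucleotide strings; every pool member is
    keyed by ``(root index, sorted tuple of substituted positions)``.  ``a``
    are proportional abundances, ``A`` absolute copy numbers, ``p`` the
    (inherited) amplification efficiencies and ``origin`` the reference each
    lineage descends from.
    """

    roots: list[str]
    a: np.ndarray
    A: np.ndarray
    p: np.ndarray
    root_id: list[int]
    muts: list[tuple[int, ...]]
    origin: list[int]
    index: dict = field(repr=False, default_factory=dict)
    cycles_done: int = 0

    @property
    def n(self) -> int:
        return len(self.muts)

    @property
    def is_true(self) -> np.ndarray:
        return np.fromiter((len(m) == 0 for m in self.muts), dtype=bool, count=self.n)

    def sequence(self, i: int) -> str:
        """Materialise the nucleotide string of pool member ``i``."""
        seq = list(self.roots[self.root_id[i]])
        for pos in self.muts[i]:
            seq[pos] = _TRANSITION[seq[pos]]
        return "".join(seq)


@dataclass
class SummaryStats:
    mean: float
    sd: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReplicateSummary:
    """Across-replicate statistics of observed (post-sequencing) sequences.

    ``unique_errors`` summarises the per-replicate count of observed unique
    error sequences; ``error_reads`` and ``true_reads`` summarise read counts
    pooled over all observed sequences of that class across replicates.
    """

    n_reps: int
    unique_errors: SummaryStats
    error_reads: SummaryStats
    true_reads: SummaryStats
    unique_errors_per_rep: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "unique_errors": self.unique_errors.to_dict(),
            "error_reads": self.error_reads.to_dict(),
            "true_reads": self.true_reads.to_dict(),
            "unique_errors_per_rep": list(self.unique_errors_per_rep),
        }


@dataclass
class SimResult:
    """Observed outcome of one simulated run: a one-sample ASV table plus truth."""

    table: ASVTable
    is_true: np.ndarray
    config: SimConfig

    @property
    def true_counts(self) -> np.ndarray:
        return self.table.total[self.is_true]

    @property
    def error_counts(self) -> np.ndarray:
        return self.table.total[~self.is_true]


def _random_sequences(n: int, length: int, gc: float, rng: np.random.Generator) -> list[str]:
    """Random sequences with an exact per-sequence G+C count of round(gc*length)."""
    n_gc = int(round(gc * length))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        order = rng.permutation(length)
        bases = np.empty(length, dtype="U1")
        bases[order[:n_gc]] = rng.choice(np.array(["G", "C"]), size=n_gc)
        bases[order[n_gc:]] = rng.choice(np.array(["A", "T"]), size=length - n_gc)
        seq = "".join(bases)
        if seq not in seen:  # collision at 160 bp is vanishingly unlikely
            seen.add(seq)
            out.append(seq)
    return out


def make_reference_pool(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Initial template pool: random reference variants with Dirichlet proportions."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    roots = _random_sequences(cfg.n_true, cfg.seq_len, cfg.gc, rng)
    a0 = rng.dirichlet(np.full(cfg.n_true, cfg.gamma))
    A0 = np.floor(cfg.pool_reads * a0).astype(np.int64)
    p = draw_efficiencies(cfg, rng, size=cfg.n_true)
    state = SimState(
        roots=roots,
        a=a0.astype(np.float64),
        A=A0,
        p=p,
        root_id=list(range(cfg.n_true)),
        muts=[()] * cfg.n_true,
        origin=list(range(cfg.n_true)),
    )
    state.index = {(r, ()): i for i, r in enumerate(state.root_id)}
    return state


def draw_efficiencies(
    cfg: SimConfig, rng: np.random.Generator | None = None, size: int | None = None
) -> np.ndarray:
    """Per-sequence amplification efficiencies, i.i.d. Beta(eff_alpha, eff_beta)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return rng.beta(cfg.eff_alpha, cfg.eff_beta, size=cfg.n_true if size is None else size)


def _toggle(muts: tuple[int, ...], pos: int) -> tuple[int, ...]:
    # transitions are involutions: a second hit at the same position reverts
    if pos in muts:
        return tuple(q for q in muts if q != pos)
    out = list(muts)
    out.append(pos)
    out.sort()
    return tuple(out)


def pcr_cycle(state: SimState, cfg: SimConfig, rng: np.random.Generator) -> SimState:
    """One PCR cycle, in place: amplification, artefact generation, dereplication."""
    n = state.n
    L = cfg.seq_len
    S = float(state.a.sum())
    if cfg.eps_per_sequence:
        eps = rng.lognormal(cfg.eps_mu, cfg.eps_sigma, size=n)
    else:
        eps = float(rng.lognormal(cfg.eps_mu, cfg.eps_sigma))
    xi = float(rng.beta(cfg.err_alpha, cfg.err_beta))

    gain = state.p * eps
    a_new = state.a * gain / S
    if cfg.growth == "exponential":
        A_new = np.floor(state.A * gain).astype(np.int64)
    elif cfg.growth == "competitive":
        A_new = np.floor(state.A * gain / S).astype(np.int64)
    else:  # literal
        A_new = np.floor(state.A * a_new).astype(np.int64)
    E = np.floor(L * A_new * xi).astype(np.int64)

    state.a = state.a + a_new
    state.A = state.A + A_new

    active = np.flatnonzero(E > 0)
    if active.size:
        counts = rng.multinomial(E[active], np.full(L, 1.0 / L))
        # per-copy proportional abundance e'_ij / E'_ij of artefacts of parent i
        unit = L * a_new[active] * xi / E[active]
        par_loc, positions = np.nonzero(counts)
        copies = counts[par_loc, positions]
        parents = active[par_loc]
        d_a = copies * unit[par_loc]

        index = state.index
        root_id = state.root_id
        muts = state.muts
        origin = state.origin
        p_arr = state.p
        old_idx: list[int] = []
        old_da: list[float] = []
        old_dA: list[int] = []
        new_a: list[float] = []
        new_A: list[int] = []
        new_p: list[float] = []
        new_root: list[int] = []
        new_muts: list[tuple[int, ...]] = []
        new_origin: list[int] = []
        next_idx = n
        for parent, pos, c, da in zip(
            parents.tolist(), positions.tolist(), copies.tolist(), d_a.tolist()
        ):
            key = (root_id[parent], _toggle(muts[parent], pos))
            idx = index.get(key)
            if idx is None:
                index[key] = next_idx
                next_idx += 1
                new_a.append(da)
                new_A.append(c)
                new_p.append(float(p_arr[parent]))
                new_root.append(key[0])
                new_muts.append(key[1])
                new_origin.append(origin[parent])
            elif idx >= n:
                j = idx - n
                new_a[j] += da
                new_A[j] += c
            else:
                old_idx.append(idx)
                old_da.append(da)
                old_dA.append(c)
        if old_idx:
            np.add.at(state.a, old_idx, old_da)
            np.add.at(state.A, old_idx, old_dA)
        if new_a:
            state.a = np.concatenate([state.a, np.asarray(new_a)])
            state.A = np.concatenate([state.A, np.asarray(new_A, dtype=np.int64)])
            state.p = np.concatenate([state.p, np.asarray(new_p)])
            state.root_id.extend(new_root)
            state.muts.extend(new_muts)
            state.origin.extend(new_origin)
    state.cycles_done += 1
    return state


def run_pcr(state: SimState, cfg: SimConfig, rng: np.random.Generator) -> SimState:
    """Apply ``cfg.n_cycles`` PCR cycles."""
    for _ in range(cfg.n_cycles):
        pcr_cycle(state, cfg, rng)
    return state


def sequence_amplicons(
    state: SimState, cfg: SimConfig, rng: np.random.Generator
) -> SimResult:
    """Multinomial sequencing of the final pool; unobserved sequences are dropped."""
    probs = state.a / state.a.sum()
    reads = rng.multinomial(cfg.n_seq_reads, probs)
    observed = np.flatnonzero(reads > 0)
    is_true = np.fromiter((len(state.muts[i]) == 0 for i in observed), dtype=bool,
                          count=observed.size)
    width = max(4, len(str(observed.size)))
    ids = [f"sv{j + 1:0{width}d}" for j in range(observed.size)]
    seqs = {ids[j]: state.sequence(int(i)) for j, i in enumerate(observed)}
    table = ASVTable(ids, reads[observed][:, None], ["sim"], seqs)
    return SimResult(table=table, is_true=is_true, config=cfg)


def simulate(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Run one full simulation (pool -> PCR -> sequencing).

    ``seed`` overrides ``cfg.seed``; a fixed seed makes the result fully
    deterministic.
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    state = make_reference_pool(cfg, rng)
    run_pcr(state, cfg, rng)
    return sequence_amplicons(state, cfg, rng)


def _stats(values: np.ndarray) -> SummaryStats:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return SummaryStats(float("nan"), float("nan"), float("nan"), float("nan"))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return SummaryStats(float(values.mean()), sd, float(values.min()), float(values.max()))


def run_replicates(
    cfg: SimConfig,
    n_reps: int = 100,
    seed: int | None = None,
    keep_results: bool = False,
) -> ReplicateSummary | tuple[ReplicateSummary, list[SimResult]]:
    """Independent seeded replicates of the simulation with pooled summaries.

    Child seeds are spawned from ``seed`` (or ``cfg.seed``) so replicates are
    independent but reproducible.
    """
    base = cfg.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(base).spawn(n_reps)
    n_err: list[int] = []
    err_reads: list[np.ndarray] = []
    true_reads: list[np.ndarray] = []
    results: list[SimResult] = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        state = make_reference_pool(cfg, rng)
        run_pcr(state, cfg, rng)
        res = sequence_amplicons(state, cfg, rng)
        n_err.append(int((~res.is_true).sum()))
        err_reads.append(res.error_counts)
        true_reads.append(res.true_counts)
        if keep_results:
            results.append(res)
    summary = ReplicateSummary(
        n_reps=n_reps,
        unique_errors=_stats(np.asarray(n_err)),
        error_reads=_stats(np.concatenate(err_reads)),
        true_reads=_stats(np.concatenate(true_reads)),
        unique_errors_per_rep=n_err,
    )
    return (summary, results) if keep_results else summary


def density_summary(result: SimResult, n_bins: int = 40, n_grid: int = 256) -> pd.DataFrame:
    """Histogram and Gaussian-kernel density of log10 read counts, per class.

    Returns a long-format, plot-ready table with columns ``asv_class``
    (true/error), ``kind`` (hist/kde), ``x`` and ``density``.  Each class's
    histogram and kernel density integrate to one.
    """
    rows: list[pd.DataFrame] = []
    for label, counts in (("true", result.true_counts), ("error", result.error_counts)):
        if counts.size == 0:
            continue
        x = np.log10(counts.astype(float))
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)
        dens, _ = np.histogram(x, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rows.append(pd.DataFrame(
            {"asv_class": label, "kind": "hist", "x": centers, "density": dens}
        ))
        if x.size > 1 and np.std(x) > 0:
            kde = gaussian_kde(x)
            bw = kde.covariance_factor() * float(np.std(x))
            grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, n_grid)
            rows.append(pd.DataFrame(
                {"asv_class": label, "kind": "kde", "x": grid, "density": kde(grid)}
            ))
    if not rows:
        return pd.DataFrame(columns=["asv_class", "kind", "x", "density"])
    return pd.concat(rows, ignore_index=True)
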