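"""Marker-conditional IBD relationship matrices by MCMC over segregation indicators.

At every scan-grid position the IBD matrix G(p) collects, for each pair of
individuals, the posterior mean of half the number of IBD gamete pairs
(diagonal 1 + P(the individual's two gametes are IBD)).  Founder gametes are
mutually non-IBD regardless of parental line, reflecting expected allele
heterogeneity within the outbred founder lines.  Sampling is a fixed-
dimension Metropolis chain over segregation indicators whose stationary law
is the Haldane transmission prior restricted to genotype-consistent descent
states; chains run per linkage group with seeds derived from the master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _descent
from .core import GeneticMap, GenotypeTable, Pedigree, RelationshipMatrix


def haldane(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction r(d) = (1 - exp(-2d/100))/2 for d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class IbdRunConfig:
    iterations: int = 20_000
    burn_in: int = 2_000
    thinning: int = 10
    seed: int = 0
    grid_step: float = 4.0
    segment_proposal_prob: float = 0.3
    max_init_restarts: int = 500

    def __post_init__(self):
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


class DescentState:
    """Segregation indicators for one linkage group: array (n_loci, n_meioses)."""

    def __init__(self, group: str, positions: np.ndarray, indicators: np.ndarray):
        self.group = group
        self.positions = np.asarray(positions, dtype=float)
        self.indicators = np.ascontiguousarray(indicators, dtype=np.uint8)
        if self.indicators.shape[0] != len(self.positions):
            raise ValueError("one indicator row per locus required")


def _pedigree_arrays(pedigree: Pedigree):
    return (
        np.ascontiguousarray(pedigree.sire_idx),
        np.ascontiguousarray(pedigree.dam_idx),
        np.ascontiguousarray(pedigree.founder_ord),
        np.ascontiguousarray(pedigree.nonfounder_ord),
    )


class _Workspace:
    """Preallocated scratch arrays for the numba kernels."""

    def __init__(self, n: int, n_slots: int):
        self.active = np.ones(n, dtype=np.bool_)
        self.fp = np.zeros(n, dtype=np.int64)
        self.fm = np.zeros(n, dtype=np.int64)
        self.forced = np.zeros(n_slots, dtype=np.int32)
        self.eu = np.zeros(n, dtype=np.int32)
        self.ev = np.zeros(n, dtype=np.int32)
        self.ea = np.zeros(n, dtype=np.int32)
        self.eb = np.zeros(n, dtype=np.int32)
        self.head = np.full(n_slots, -1, dtype=np.int32)
        self.nxt = np.full(2 * n, -1, dtype=np.int32)
        self.eind = np.zeros(2 * n, dtype=np.int32)
        self.stack = np.zeros(n_slots, dtype=np.int32)
        self.trail = np.zeros(n_slots, dtype=np.int32)

    def args(self):
        return (
            self.fp, self.fm, self.forced, self.eu, self.ev, self.ea, self.eb,
            self.head, self.nxt, self.eind, self.stack, self.trail,
        )


def _group_alleles(pedigree: Pedigree, genotypes: GenotypeTable, gmap: GeneticMap, group: str):
    g = gmap.group(group)
    markers = [m for m in g.markers if m in genotypes.markers]
    pos = np.array([p for m, p in zip(g.markers, g.positions) if m in genotypes.markers])
    aligned = genotypes.aligned_to(pedigree, markers)
    a1 = np.ascontiguousarray(aligned[:, :, 0])
    a2 = np.ascontiguousarray(aligned[:, :, 1])
    return markers, pos, a1, a2


def prior_logprob(state: DescentState, gmap: GeneticMap) -> float:
    """Log-prior of a descent state: uniform first locus, Haldane Markov chain after.

    Per meiosis: log(1/2) + sum over adjacent loci of log r or log(1-r)."""
    pos = state.positions
    S = state.indicators
    n_mei = S.shape[1]
    total = n_mei * np.log(0.5)
    r = haldane(np.diff(pos))
    for l in range(len(pos) - 1):
        switches = int(np.sum(S[l] != S[l + 1]))
        total += switches * np.log(r[l]) + (n_mei - switches) * np.log1p(-r[l])
    return float(total)


def is_consistent(
    state: DescentState,
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    locus: str,
    gmap: GeneticMap | None = None,
) -> bool:
    """True iff some founder-allele assignment reproduces all observed genotypes
    under the descent graph at ``locus``."""
    aligned = genotypes.aligned_to(pedigree, [locus])
    a1 = np.ascontiguousarray(aligned[:, 0, 0])
    a2 = np.ascontiguousarray(aligned[:, 0, 1])
    n_slots = 2 * pedigree.n_founders
    ws = _Workspace(pedigree.n, n_slots)
    # position of the locus within the state's loci
    li = 0
    if gmap is not None:
        g = gmap.group(state.group)
        li = g.markers.index(locus)
        li = int(np.argmin(np.abs(state.positions - g.positions[li])))
    s_loc = np.ascontiguousarray(state.indicators[li])
    sire, dam, fo, nf = _pedigree_arrays(pedigree)
    return bool(
        _descent.locus_consistent(
            sire, dam, fo, nf, s_loc, a1, a2, ws.active, n_slots, *ws.args()
        )
    )


@dataclass
class DescentSamples:
    """Retained MCMC descent states for one linkage group."""

    group: str
    marker_positions: np.ndarray  # cM of the sampled loci
    samples: np.ndarray  # (n_samples, n_loci, n_meioses) uint8
    pedigree: Pedigree
    config: IbdRunConfig
    acceptance_rate: float = float("nan")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def mcmc_sample(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    gmap: GeneticMap,
    config: IbdRunConfig,
    group: str,
    seed: int | None = None,
) -> DescentSamples:
    """Sample descent states for one linkage group.

    Deterministic given (inputs, seed).  Raises if no genotype-consistent
    initial state can be found (corrupted genotypes)."""
    markers, pos, a1, a2 = _group_alleles(pedigree, genotypes, gmap, group)
    L = len(markers)
    if L == 0:
        raise ValueError(f"no genotyped markers on group {group!r}")
    n_slots = 2 * pedigree.n_founders
    ws = _Workspace(pedigree.n, n_slots)
    sire, dam, fo, nf = _pedigree_arrays(pedigree)
    n_mei = pedigree.n_meioses
    if seed is None:
        seed = config.seed
    seed = int(seed) % (2**31 - 1)

    S = np.zeros((L, n_mei), dtype=np.uint8)
    _descent.seed_rng(seed)
    for l in range(L):
        ok = _descent.init_locus(
            sire, dam, fo, nf, S[l], np.ascontiguousarray(a1[:, l]),
            np.ascontiguousarray(a2[:, l]), config.max_init_restarts, n_slots,
            ws.active, *ws.args(),
        )
        if not ok:
            raise RuntimeError(
                f"no consistent descent state found for {markers[l]!r} on group {group!r}; "
                "genotypes are likely Mendelian-inconsistent"
            )

    r = haldane(np.diff(pos))
    log_r = np.log(np.maximum(r, 1e-300))
    log_1mr = np.log1p(-np.minimum(r, 1 - 1e-15))
    out = np.zeros((config.n_samples, L, n_mei), dtype=np.uint8)
    ws.active[:] = True
    ns, proposed, accepted = _descent.mcmc_run(
        sire, dam, fo, nf, a1, a2, log_r, log_1mr, S,
        config.iterations, config.burn_in, config.thinning,
        config.segment_proposal_prob, seed + 1, n_slots, out,
        ws.active, *ws.args(),
    )
    return DescentSamples(
        group=group,
        marker_positions=pos,
        samples=out[:ns],
        pedigree=pedigree,
        config=config,
        acceptance_rate=accepted / max(proposed, 1),
    )


def _bridge_probs(dl: float, dr: float) -> tuple[float, float]:
    """(P(keep | flanks equal), P(equal left | flanks differ)) for a Markov bridge."""
    r1 = float(haldane(dl))
    r2 = float(haldane(dr))
    r12 = r1 * (1 - r2) + r2 * (1 - r1)
    if r12 <= 0:
        return 1.0, 1.0
    p_same = (1 - r1) * (1 - r2) / (1 - r12)
    p_left = (1 - r1) * r2 / r12
    return p_same, p_left


def ibd_matrix_at(
    samples: DescentSamples,
    position: float,
    subjects: list[str],
    seed: int | None = None,
    block: int = 256,
) -> RelationshipMatrix:
    """IBD relationship matrix at a grid position from retained samples.

    Descent at off-marker positions is drawn per sample through the Markov
    bridge between flanking-marker indicators; founder gametes are mutually
    non-IBD; entry(i,j) = mean over samples of half the count of IBD gamete
    pairs, diagonal = 1 + P(own gametes IBD)."""
    ped = samples.pedigree
    pos = samples.marker_positions
    if position < pos[0] - 1e-9 and position < 0:
        raise ValueError("position below 0 cM")
    S = samples.samples
    n_samples, L, n_mei = S.shape
    if n_samples == 0:
        raise ValueError("no retained samples")
    subj_idx = ped.indices(subjects)
    n_subj = len(subj_idx)
    n_slots = 2 * ped.n_founders
    sire, dam, fo, nf = _pedigree_arrays(ped)

    # flanking loci
    at = np.nonzero(np.abs(pos - position) < 1e-6)[0]
    if at.size:
        lidx = ridx = int(at[0])
        p_same, p_left = 1.0, 1.0
    else:
        left = np.nonzero(pos < position)[0]
        right = np.nonzero(pos > position)[0]
        if left.size and right.size:
            lidx, ridx = int(left[-1]), int(right[0])
            p_same, p_left = _bridge_probs(position - pos[lidx], pos[ridx] - position)
        elif right.size:
            lidx, ridx = -1, int(right[0])
            p_same, p_left = 1.0 - float(haldane(pos[ridx] - position)), 1.0
        else:
            lidx, ridx = int(left[-1]), -1
            p_same, p_left = 1.0 - float(haldane(position - pos[lidx])), 1.0

    if seed is None:
        seed = samples.config.seed
    seed = (int(seed) + 1_000_003 * (int(round(position * 64)) + 7)) % (2**31 - 1)

    fp = np.zeros(ped.n, dtype=np.int64)
    fm = np.zeros(ped.n, dtype=np.int64)
    M = np.zeros((n_subj, n_subj))
    ind = np.zeros((min(block, n_samples), n_mei), dtype=np.uint8)
    for start in range(0, n_samples, block):
        nb = min(block, n_samples - start)
        if lidx == ridx and lidx >= 0:
            ind_blk = S[start : start + nb, lidx, :]
        else:
            _descent.bridge_indicators(
                S[start : start + nb], lidx, ridx, p_same, p_left, seed + start, ind[:nb]
            )
            ind_blk = ind[:nb]
        C = np.zeros((n_subj, n_slots * nb), dtype=np.float32)
        _descent.fill_slot_counts(
            sire, dam, fo, nf, np.ascontiguousarray(ind_blk), subj_idx, fp, fm, C, n_slots
        )
        M += (C @ C.T).astype(np.float64)
    M /= 2.0 * n_samples
    return RelationshipMatrix(
        tuple(str(s) for s in subjects), M, role="ibd-at-position",
        position=(samples.group, float(position)),
    )


class IbdStore:
    """Per-position IBD matrices for one run, keyed by (group, position cM).

    One ordered id list; dense symmetric matrices; persisted as a single
    ``.npz`` archive so thresholds/scans can reuse matrices across thousands
    of phenotype replicates."""

    def __init__(self, ids: list[str]):
        self.ids = [str(i) for i in ids]
        self._entries: dict[tuple[str, float], np.ndarray] = {}

    def put(self, group: str, position: float, matrix: RelationshipMatrix | np.ndarray) -> None:
        values = matrix.values if isinstance(matrix, RelationshipMatrix) else np.asarray(matrix)
        if values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix does not match the store's id list")
        self._entries[(group, round(float(position), 6))] = values

    def get(self, group: str, position: float) -> RelationshipMatrix:
        key = (group, round(float(position), 6))
        return RelationshipMatrix(
            tuple(self.ids), self._entries[key], role="ibd-at-position", position=key
        )

    def positions(self, group: str) -> np.ndarray:
        return np.array(sorted(p for g, p in self._entries if g == group))

    @property
    def groups(self) -> list[str]:
        return sorted({g for g, _ in self._entries})

    def save(self, path) -> None:
        arrays = {"__ids__": np.array(self.ids)}
        for (g, p), m in self._entries.items():
            arrays[f"{g}@{p}"] = m
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "IbdStore":
        with np.load(path, allow_pickle=False) as z:
            store = cls([str(i) for i in z["__ids__"]])
            for k in z.files:
                if k == "__ids__":
                    continue
                g, p = k.rsplit("@", 1)
                store._entries[(g, round(float(p), 6))] = z[k]
        return store

    def export_tsv(self, group: str, position: float, path) -> None:
        import pandas as pd

        m = self.get(group, position)
        pd.DataFrame(m.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def compute_ibd_store(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    gmap: GeneticMap,
    subjects: list[str],
    config: IbdRunConfig,
    groups: list[str] | None = None,
    extra_positions: dict[str, list[float]] | None = None,
) -> IbdStore:
    """Run per-group chains and fill an IbdStore on the scan grid.

    Grid = every ``config.grid_step`` cM plus any declared extra positions
    (e.g. causal-locus coordinates); per-group seeds derive from the master
    seed by group index."""
    store = IbdStore(list(subjects))
    names = groups if groups is not None else gmap.group_names
    extra_positions = extra_positions or {}
    for gi, gname in enumerate(names):
        samples = mcmc_sample(
            pedigree, genotypes, gmap, config, gname, seed=config.seed + 10_007 * gi
        )
        grid = gmap.grid(gname, extra=extra_positions.get(gname, ()), step=config.grid_step)
        for p in grid:
            store.put(gname, p, ibd_matrix_at(samples, float(p), list(subjects)))
    return store
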