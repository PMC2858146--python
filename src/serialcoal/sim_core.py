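"""Serial-coalescent genealogy simulation with mutation overlay.

The serial (heterochronous) coalescent generalizes the Kingman coalescent to
samples collected at different times: lineages enter the genealogy at their
tip ages and, while ``j`` lineages are active, pairs coalesce at instantaneous
rate C(j,2)/N(t), where N(t) is the (haploid) effective number of gene copies
``t`` generations before the most recent sample.  This module simulates dated
genealogies under constant or exponentially changing demography and overlays
transition-biased finite-sites (or infinite-sites) mutations, producing the
haplotype alignments consumed by the neutrality-test and divergence modules.

Time convention: t = 0 at the youngest tip, increasing into the past, in units
of generations.  Ages supplied in years BP are shifted so the youngest tip
sits at the origin and divided by the generation time (no rounding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import comb, exp, inf, isfinite, log

import numpy as np

__all__ = [
    "Demography",
    "SampleSchedule",
    "Genealogy",
    "MutationModel",
    "HaplotypeAlignment",
    "default_het_ages",
    "coalescent_interval",
    "simulate_genealogy",
    "overlay_mutations",
    "export_newick",
    "export_fasta",
    "generate_structured_dataset",
]

BASES = "ACGT"
# transitions: A<->G (0<->2), C<->T (1<->3)
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def default_het_ages() -> list[float]:
    """The default 37-tip heterochronous age fixture (years BP).

    37 ages evenly spaced over the Holocene span 2,000..12,000 years BP,
    emulating a serial ancient-mtDNA collection.  Shipped as an editable JSON
    file so alternative radiocarbon schedules can be dropped in.
    """
    text = resources.files("serialcoal").joinpath("data/default_het_ages.json").read_text()
    return list(json.loads(text)["ages_bp"])


@dataclass(frozen=True)
class Demography:
    """Backward-time effective-size trajectory N(t) = max(N0*exp(-g*t), floor).

    Parameters
    ----------
    N0 : float
        Effective number of gene copies at the most recent sampling time
        (haploid scale, appropriate for mtDNA).
    g : float
        Exponential rate per generation on the forward-time scale; positive g
        means the population grew forward in time, i.e. shrinks backward.
    floor_size : float
        Minimal size the trajectory is clamped to (keeps coalescence rates
        finite under strong decline).
    """

    N0: float
    g: float = 0.0
    floor_size: float = 1.0

    def __post_init__(self) -> None:
        if not (isfinite(self.N0) and self.N0 >= 2):
            raise ValueError(f"N0 must be finite and >= 2, got {self.N0}")
        if self.floor_size < 1:
            raise ValueError(f"floor_size must be >= 1, got {self.floor_size}")
        if not isfinite(self.g):
            raise ValueError("g must be finite")

    def size_at(self, t: float) -> float:
        """N(t) for t generations before the most recent sample."""
        return max(self.N0 * exp(-self.g * t), self.floor_size)


@dataclass(frozen=True)
class SampleSchedule:
    """Tip ages (years BP) plus a generation time, defining the sampling scheme."""

    ages_bp: tuple[float, ...]
    generation_time: float = 7.0

    def __init__(self, ages_bp, generation_time: float = 7.0) -> None:
        ages = tuple(float(a) for a in ages_bp)
        if len(ages) < 1:
            raise ValueError("schedule needs at least one tip")
        if any(a < 0 or not isfinite(a) for a in ages):
            raise ValueError("all ages must be finite and >= 0")
        if generation_time <= 0:
            raise ValueError("generation_time must be positive")
        object.__setattr__(self, "ages_bp", ages)
        object.__setattr__(self, "generation_time", float(generation_time))

    @property
    def n(self) -> int:
        return len(self.ages_bp)

    @property
    def is_isochronous(self) -> bool:
        return len(set(self.ages_bp)) == 1

    def tip_times(self) -> np.ndarray:
        """Tip times in generations before the youngest tip (youngest at 0)."""
        ages = np.asarray(self.ages_bp, dtype=float)
        return (ages - ages.min()) / self.generation_time

    @classmethod
    def isochronous(cls, n: int, generation_time: float = 7.0) -> "SampleSchedule":
        return cls((0.0,) * n, generation_time)

    @classmethod
    def default_heterochronous(cls, generation_time: float = 7.0) -> "SampleSchedule":
        return cls(default_het_ages(), generation_time)


@dataclass
class Genealogy:
    """A dated binary genealogy: 2n-1 nodes, tips 0..n-1, root last.

    ``time`` is in generations before the youngest tip; every parent is
    strictly older than its children (tips may be internal in age order but
    never older than their ancestors).
    """

    n: int
    time: np.ndarray
    parent: np.ndarray
    children: list[tuple[int, int] | None]
    labels: list[str]

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        lens = self.time[self.parent[:-1]] - self.time[:-1]
        return np.asarray(lens, dtype=float)

    def tip_masks(self) -> np.ndarray:
        """(2n-1, n) boolean matrix: tips descending from each node."""
        masks = np.zeros((2 * self.n - 1, self.n), dtype=bool)
        for i in range(self.n):
            masks[i, i] = True
        for i in range(self.n, 2 * self.n - 1):
            a, b = self.children[i]  # type: ignore[misc]
            masks[i] = masks[a] | masks[b]
        return masks

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


@dataclass(frozen=True)
class MutationModel:
    """Per-site mutation process: rate, length, transition bias, site model.

    ``mu_per_site_year`` is converted to a per-generation rate internally via
    the schedule's generation time.  ``mode`` is ``"finite"`` (360-bp style
    {A,C,G,T} sequences with recurrent hits allowed) or ``"infinite"`` (every
    mutation creates a new segregating site; ``ts_probability`` is ignored).
    """

    mu_per_site_year: float = 7.6e-7
    L: int = 360
    ts_probability: float = 50.0 / 51.0
    mode: str = "finite"

    def __post_init__(self) -> None:
        if self.mu_per_site_year < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0.0 <= self.ts_probability <= 1.0:
            raise ValueError("ts_probability must be in [0, 1]")
        if self.mode not in ("finite", "infinite"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class HaplotypeAlignment:
    """Simulated haplotypes: sequence strings (finite) or a binary site matrix."""

    sample_ids: list[str]
    sequences: list[str] | None = None
    site_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.sequences is None) == (self.site_matrix is None):
            raise ValueError("provide exactly one of sequences / site_matrix")
        if self.sequences is not None:
            if len({len(s) for s in self.sequences}) > 1:
                raise ValueError("ragged alignment")
            if len(self.sequences) != len(self.sample_ids):
                raise ValueError("ids do not match sequences")
        else:
            if self.site_matrix.shape[0] != len(self.sample_ids):
                raise ValueError("ids do not match matrix rows")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_matrix(self) -> np.ndarray:
        """Integer (n, L) matrix: base codes 0..3 (finite) or 0/1 (infinite)."""
        if self.site_matrix is not None:
            return self.site_matrix.astype(np.uint8)
        arr = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        arr = arr.reshape(self.n, -1).copy()
        out = np.zeros_like(arr)
        for code, base in enumerate(BASES):
            out[arr == ord(base)] = code
        return out


def coalescent_interval(j: int, t0: float, demography: Demography, rng: np.random.Generator) -> float:
    """Waiting time (generations) until the next coalescence among ``j`` lineages.

    Draws from the inhomogeneous exponential with rate C(j,2)/N(t0 + s),
    N(t) = max(N0*exp(-g t), floor), by inverting the integrated hazard in
    closed form.  Returns ``inf`` when the cumulative hazard is bounded (a
    population growing backward in time may never coalesce).
    """
    if j < 2:
        raise ValueError(f"need at least two lineages, got j={j}")
    if not isfinite(t0) or t0 < 0:
        raise ValueError(f"t0 must be finite and >= 0, got {t0}")
    c = comb(j, 2)
    e = rng.exponential()
    g, N0, floor = demography.g, demography.N0, demography.floor_size
    if g == 0.0:
        return e * N0 / c
    if g > 0:
        # size shrinks backward, reaching the floor at t_f
        t_f = log(N0 / floor) / g if N0 > floor else 0.0
        if t0 >= t_f:
            return e * floor / c
        # hazard over [t0, t_f): (c/N0) * e^{g t}
        h_exp = c / (N0 * g) * (exp(g * t_f) - exp(g * t0))
        if e <= h_exp:
            return log(exp(g * t0) + e * N0 * g / c) / g - t0
        return (t_f - t0) + (e - h_exp) * floor / c
    # g < 0: size grows backward without bound; total hazard is finite
    h_total = c / (N0 * (-g)) * exp(g * t0)
    if e >= h_total:
        return inf
    return log(exp(g * t0) + e * N0 * g / c) / g - t0


def simulate_genealogy(schedule: SampleSchedule, demography: Demography, seed) -> Genealogy:
    """Simulate a serial-coalescent genealogy over the scheduled tips.

    Lineages are activated at their tip times; between successive sampling
    times a candidate coalescence is drawn via :func:`coalescent_interval`
    among the active lineages, and overshooting candidates are discarded in
    favour of advancing to the next sampling time (valid by the memoryless
    construction of the inhomogeneous process).  Identical ``(inputs, seed)``
    yield an identical tree.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n
    tip_times = schedule.tip_times()
    labels = [f"t{i}" for i in range(n)]

    time = np.zeros(2 * n - 1 if n > 1 else 1, dtype=float)
    time[:n] = tip_times
    parent = np.full(time.shape, -1, dtype=np.int64)
    children: list[tuple[int, int] | None] = [None] * time.shape[0]

    if n == 1:
        return Genealogy(n=1, time=time, parent=parent, children=children, labels=labels)

    order = np.argsort(tip_times, kind="stable")
    pending = list(order)  # tips not yet entered, in age order
    active: list[int] = []
    t = float(tip_times[order[0]])
    while pending and tip_times[pending[0]] <= t:
        active.append(int(pending.pop(0)))
    next_node = n
    while len(active) + len(pending) > 1 or pending:
        next_sample = float(tip_times[pending[0]]) if pending else inf
        if len(active) >= 2:
            dt = coalescent_interval(len(active), t, demography, rng)
            if t + dt < next_sample:
                t = t + dt
                i = int(rng.integers(len(active)))
                a = active.pop(i)
                jdx = int(rng.integers(len(active)))
                b = active.pop(jdx)
                time[next_node] = t
                children[next_node] = (a, b)
                parent[a] = next_node
                parent[b] = next_node
                active.append(next_node)
                next_node += 1
                if len(active) == 1 and not pending:
                    break
                continue
        if not pending:  # pragma: no cover - unreachable: <2 active implies pending
            raise RuntimeError("coalescent stalled")
        t = next_sample
        while pending and tip_times[pending[0]] <= t:
            active.append(int(pending.pop(0)))
    return Genealogy(n=n, time=time, parent=parent, children=children, labels=labels)


def _apply_mutation(base: int, model: MutationModel, rng: np.random.Generator) -> int:
    if rng.random() < model.ts_probability:
        return int(_TRANSITION[base])
    return int(_TRANSVERSIONS[base][rng.integers(2)])


def overlay_mutations(
    genealogy: Genealogy, model: MutationModel, seed, generation_time: float = 7.0
) -> HaplotypeAlignment:
    """Drop mutations on the genealogy and return the tip alignment.

    Per-branch mutation counts are Poisson with mean
    ``branch_length_generations * mu_per_generation * L`` where the
    per-generation rate is ``mu_per_site_year * generation_time`` (branch
    lengths are in generations, the rate is quoted per year).  Finite-sites
    events pick a transition with probability ``ts_probability``, otherwise
    one of the two transversions uniformly; the root sequence is uniform over
    {A,C,G,T} per site.  Infinite-sites events each open a fresh column of
    the binary matrix (all-ancestral root).
    """
    return _overlay(genealogy, model, mutation_rate_per_gen(model, generation_time), seed)


def mutation_rate_per_gen(model: MutationModel, generation_time: float = 7.0) -> float:
    """Per-site per-generation mutation rate implied by the model."""
    return model.mu_per_site_year * generation_time


def _overlay(
    genealogy: Genealogy, model: MutationModel, mu_gen: float, seed,
    root_seq: np.ndarray | None = None,
) -> HaplotypeAlignment:
    rng = np.random.default_rng(seed)
    n = genealogy.n
    ids = list(genealogy.labels)
    if n == 1:
        if model.mode == "infinite":
            return HaplotypeAlignment(sample_ids=ids, site_matrix=np.zeros((1, 0), dtype=np.uint8))
        base = rng.integers(0, 4, model.L) if root_seq is None else root_seq
        seq = "".join(BASES[b] for b in base)
        return HaplotypeAlignment(sample_ids=ids, sequences=[seq])

    lens = genealogy.branch_lengths()  # generations, one per non-root node
    counts = rng.poisson(lens * mu_gen * model.L)

    if model.mode == "infinite":
        masks = genealogy.tip_masks()
        total = int(counts.sum())
        mat = np.zeros((n, total), dtype=np.uint8)
        col = 0
        for node in range(2 * n - 2):
            for _ in range(int(counts[node])):
                mat[masks[node], col] = 1
                col += 1
        return HaplotypeAlignment(sample_ids=ids, site_matrix=mat)

    if root_seq is None:
        root_seq = rng.integers(0, 4, model.L)
    seqs: dict[int, np.ndarray] = {genealogy.root: np.asarray(root_seq, dtype=np.int64)}
    # preorder: parents first (root has the highest index; children lower)
    for node in range(2 * n - 3, -1, -1):
        seq = seqs[int(genealogy.parent[node])].copy()
        for site in rng.integers(0, model.L, int(counts[node])):
            seq[site] = _apply_mutation(int(seq[site]), model, rng)
        seqs[node] = seq
    strings = ["".join(BASES[b] for b in seqs[i]) for i in range(n)]
    return HaplotypeAlignment(sample_ids=ids, sequences=strings)


def simulate_alignment(
    schedule: SampleSchedule, demography: Demography, model: MutationModel, seed
) -> HaplotypeAlignment:
    """Genealogy + mutations in one call; seed split deterministically."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    tree_seed, mut_seed = ss.spawn(2)
    tree = simulate_genealogy(schedule, demography, tree_seed)
    mu_gen = model.mu_per_site_year * schedule.generation_time
    return _overlay(tree, model, mu_gen, mut_seed)


def export_newick(genealogy: Genealogy) -> str:
    """Newick string with branch lengths in generations."""
    g = genealogy
    if g.n == 1:
        return f"{g.labels[0]}:0;"

    def fmt(node: int) -> str:
        if node < g.n:
            name = g.labels[node]
        else:
            a, b = g.children[node]  # type: ignore[misc]
            name = f"({fmt(a)},{fmt(b)})"
        if node == g.root:
            return name
        blen = g.time[g.parent[node]] - g.time[node]
        return f"{name}:{blen:.10g}"

    return fmt(g.root) + ";"


def export_fasta(aln: HaplotypeAlignment, path) -> None:
    """Write a finite-sites alignment as FASTA (Biopython)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if aln.sequences is None:
        raise ValueError("only finite-sites alignments can be written as FASTA")
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, path, "fasta")


def generate_structured_dataset(
    n_per_group: tuple[int, int],
    fixed_differences: int,
    demography: Demography,
    model: MutationModel,
    seed,
    generation_time: float = 7.0,
):
    """Two independently simulated groups with forced fixed differences.

    Emulates a two-haplogroup contrast.  Both groups are sampled from one
    panmictic genealogy under the shared demography (coalescent tips are
    exchangeable, so with ``fixed_differences=0`` the grouping is a pure
    relabeling and the expected Φst is ~0 — the correct null for permutation
    calibration); ``fixed_differences`` site positions are then overwritten
    with alternative fixed states between the groups to mimic diverged
    haplogroups.  Returns ``(alignment, labels)`` with labels ``"A"``/``"B"``
    per sample.  Requires finite-sites mode (the forcing rewrites states).
    """
    if model.mode != "finite":
        raise ValueError("structured datasets require finite-sites mode")
    if not 0 <= fixed_differences <= model.L:
        raise ValueError("fixed_differences must be in [0, L]")
    ss = np.random.SeedSequence(seed)
    seed_sim, seed_sites = ss.spawn(2)
    sched = SampleSchedule.isochronous(sum(n_per_group), generation_time)
    aln = simulate_alignment(sched, demography, model, seed_sim)
    rng = np.random.default_rng(seed_sites)
    sites = rng.choice(model.L, size=fixed_differences, replace=False)
    full = aln.to_matrix()
    mats = [full[: n_per_group[0]], full[n_per_group[0] :]]
    for site in sites:
        base_a = int(rng.integers(4))
        base_b = int((base_a + 1 + rng.integers(3)) % 4)
        mats[0][:, site] = base_a
        mats[1][:, site] = base_b
    seqs, ids, labels = [], [], []
    for gi, (mat, group_label) in enumerate(zip(mats, "AB")):
        for row_i, row in enumerate(mat):
            seqs.append("".join(BASES[b] for b in row))
            ids.append(f"{group_label}{row_i}")
            labels.append(group_label)
    return HaplotypeAlignment(sample_ids=ids, sequences=seqs), labels
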