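"""Between-population divergence statistics for haplotype alignments.

Implements the statistics used to compare ancient mtDNA sequence groups:

* pairwise difference counts between aligned haplotypes (pairwise deletion
  of gaps/ambiguities);
* two-level AMOVA with the number of differences as the molecular distance,
  yielding Φst with a permutation p-value;
* pairwise Φst matrices with bootstrap standard errors (individuals are
  resampled within groups — with a single locus there is nothing else to
  resample);
* classical (Torgerson) metric MDS of a distance matrix with Kruskal
  stress-1 reported against the input distances.

The AMOVA follows the standard variance-component decomposition: with
squared distances δ²_ij between haplotypes,

    SSD_total  = (1/2N) Σ_ij δ²_ij           (all ordered pairs)
    SSD_within = Σ_k (1/2n_k) Σ_{i,j∈k} δ²_ij
    SSD_among  = SSD_total − SSD_within
    σ²_w = SSD_within/(N−K),   σ²_a = (SSD_among/(K−1) − σ²_w)/n′
    n′ = (N − Σ_k n_k²/N)/(K−1),   Φst = σ²_a/(σ²_a + σ²_w)

Here the pairwise difference count itself plays the role of δ² (the AMOVA
convention when "number of differences" is the chosen molecular distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PopulationDataset",
    "PhiStResult",
    "MdsResult",
    "read_fasta_with_metadata",
    "pairwise_differences",
    "amova_phist",
    "pairwise_phist_matrix",
    "classical_mds",
]

_VALID = frozenset(b"ACGT")


@dataclass
class PopulationDataset:
    """Aligned haplotypes with a population label (and optional age) per sample."""

    ids: list[str]
    sequences: list[str]
    labels: list[str]
    ages_bp: list[float] | None = None

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("sequences must be aligned to equal length")
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise ValueError("ids, sequences and labels must align")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l)
        return list(seen)


@dataclass
class PhiStResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    p_perm: float | None = None
    n_perm: int = 0


@dataclass
class MdsResult:
    coordinates: np.ndarray  # (n_points, dims), centroid at origin
    eigenvalues: np.ndarray
    stress: float


def read_fasta_with_metadata(fasta_path, metadata_path) -> PopulationDataset:
    """Load a FASTA alignment plus a CSV of ``id,population[,age_bp]`` rows.

    Every FASTA id must appear in the metadata and vice versa; sequence order
    follows the FASTA file.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    if "id" not in meta.columns or "population" not in meta.columns:
        raise ValueError("metadata needs 'id' and 'population' columns")
    meta = meta.set_index("id")
    fasta_ids = [r.id for r in records]
    missing = [i for i in fasta_ids if i not in meta.index]
    extra = [i for i in meta.index if i not in set(fasta_ids)]
    if missing or extra:
        raise ValueError(
            f"id mismatch between FASTA and metadata: missing from metadata {missing}, "
            f"absent from FASTA {extra}")
    ages = None
    if "age_bp" in meta.columns:
        ages = [float(meta.loc[i, "age_bp"]) for i in fasta_ids]
    return PopulationDataset(
        ids=fasta_ids,
        sequences=[str(r.seq).upper() for r in records],
        labels=[str(meta.loc[i, "population"]) for i in fasta_ids],
        ages_bp=ages,
    )


def _encode(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), -1)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    return arr, valid


def pairwise_differences(dataset: PopulationDataset) -> np.ndarray:
    """Symmetric matrix of mismatch counts, pairwise-deleting non-ACGT sites."""
    if dataset.n < 2:
        raise ValueError("need at least two samples")
    arr, valid = _encode(dataset.sequences)
    n = dataset.n
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d[i, i + 1 :] = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
    return d + d.T


def _phi_st_from_d2(d2: np.ndarray, codes: np.ndarray, K: int) -> tuple[float, float, float]:
    """Variance components from a squared-distance matrix and group codes."""
    N = len(codes)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = 0.0
    sizes = np.bincount(codes, minlength=K)
    for k in range(K):
        idx = np.flatnonzero(codes == k)
        ssd_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    msd_among = ssd_among / (K - 1)
    msd_within = ssd_within / (N - K)
    n_prime = (N - (sizes**2).sum() / N) / (K - 1)
    sigma2_w = msd_within
    sigma2_a = (msd_among - msd_within) / n_prime
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom > 0 else (1.0 if sigma2_a > 0 else 0.0)
    return float(phi), float(sigma2_a), float(sigma2_w)


def _codes(labels: list[str], groups: list[str]) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(groups)}
    return np.array([lookup[l] for l in labels])


def amova_phist(
    dataset: PopulationDataset,
    grouping: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PhiStResult:
    """Two-level AMOVA Φst with a permutation test.

    ``grouping`` optionally restricts/reorders the group labels considered
    (defaults to all groups in the dataset).  The permutation test shuffles
    individuals among groups with group sizes fixed; the p-value uses the
    plus-one estimator on ``Φst(permuted) ≥ Φst(observed)``.
    """
    groups = grouping if grouping is not None else dataset.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    keep = [i for i, l in enumerate(dataset.labels) if l in set(groups)]
    sub = PopulationDataset(
        ids=[dataset.ids[i] for i in keep],
        sequences=[dataset.sequences[i] for i in keep],
        labels=[dataset.labels[i] for i in keep],
    )
    present = set(sub.labels)
    empty = [g for g in groups if g not in present]
    if empty:
        raise ValueError(f"groups without samples: {empty}")
    if sub.n < 3:
        raise ValueError("need at least three samples")
    d2 = pairwise_differences(sub)  # difference count used as squared distance
    codes = _codes(sub.labels, list(groups))
    phi, s2a, s2w = _phi_st_from_d2(d2, codes, len(groups))
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            ph, _, _ = _phi_st_from_d2(d2, perm, len(groups))
            if ph >= phi - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return PhiStResult(phi_st=phi, sigma2_among=s2a, sigma2_within=s2w,
                       p_perm=p, n_perm=n_perm)


def pairwise_phist_matrix(
    dataset: PopulationDataset, n_boot: int = 1000, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All two-group Φst values with bootstrap standard errors.

    Returns ``(phi_df, se_df)`` indexed by group name.  The bootstrap
    resamples individuals within each group (sizes fixed) and reports the
    standard deviation of Φst over resamples; for a pair involving a
    single-sample group the SE is NaN (flagged unavailable).
    """
    groups = dataset.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    d2 = pairwise_differences(dataset)
    labels = np.array(dataset.labels)
    rng = np.random.default_rng(seed)
    phi = pd.DataFrame(0.0, index=groups, columns=groups)
    se = pd.DataFrame(0.0, index=groups, columns=groups)
    for a_i in range(len(groups)):
        for b_i in range(a_i + 1, len(groups)):
            ga, gb = groups[a_i], groups[b_i]
            ia = np.flatnonzero(labels == ga)
            ib = np.flatnonzero(labels == gb)
            idx = np.concatenate([ia, ib])
            codes = np.r_[np.zeros(len(ia), int), np.ones(len(ib), int)]
            sub_d2 = d2[np.ix_(idx, idx)]
            val, _, _ = _phi_st_from_d2(sub_d2, codes, 2)
            phi.loc[ga, gb] = phi.loc[gb, ga] = val
            if min(len(ia), len(ib)) < 2 or n_boot == 0:
                se.loc[ga, gb] = se.loc[gb, ga] = np.nan
                continue
            boots = np.empty(n_boot)
            for b in range(n_boot):
                ra = rng.integers(0, len(ia), len(ia))
                rb = len(ia) + rng.integers(0, len(ib), len(ib))
                ridx = np.concatenate([ra, rb])
                boots[b], _, _ = _phi_st_from_d2(sub_d2[np.ix_(ridx, ridx)], codes, 2)
            sd = float(np.std(boots, ddof=1))
            se.loc[ga, gb] = se.loc[gb, ga] = sd
    return phi, se


def kruskal_stress1(d_obs: np.ndarray, d_fit: np.ndarray) -> float:
    """Kruskal stress-1 between observed and embedded distances."""
    iu = np.triu_indices(d_obs.shape[0], k=1)
    num = ((d_obs[iu] - d_fit[iu]) ** 2).sum()
    den = (d_obs[iu] ** 2).sum()
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def classical_mds(distances, dims: int = 2) -> MdsResult:
    """Torgerson metric MDS of a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes, and keeps the top
    ``dims`` positive-eigenvalue axes (fewer, with a warning, if the matrix
    has fewer positive eigenvalues).  Coordinates are centered at the origin
    by construction.
    """
    import warnings

    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or (D < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.size and vals.max() > 0 else vals > 0
    n_pos = int(pos.sum())
    use = dims
    if n_pos < dims:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing dims from {dims}")
        use = n_pos
    coords = vecs[:, :use] * np.sqrt(np.maximum(vals[:use], 0.0))
    if use == 0:
        coords = np.zeros((m, 1))
    fit = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    return MdsResult(coordinates=coords, eigenvalues=vals,
                     stress=kruskal_stress1(D, fit))
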