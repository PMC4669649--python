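"""Stage I: genotype-cluster estimation from samples with known genotypes.

The known-genotype samples (HapMap-style QC replicates) are split into a
training and a testing group.  At each SNP the training genotypes decide
whether the SNP's three clusters can be estimated directly (group G1: three
distinct genotypes, each with at least three training samples) or whether the
SNP must borrow a nearby, well-behaved reference SNP (group G2).  Reference
selection projects each two-channel intensity pair onto the contrast
coordinate b = (r - g)/(r + g) and minimises a standardised distance between
the target's and each candidate's projected training profiles.  Cluster
means and covariances are then the per-genotype sample moments, pooled with
the reference's training rows for G2 targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GENOTYPES, MISSING, ClusterModel, KnownGenotypeTable

#: Minimum per-genotype training count for a SNP to qualify as G1.
MIN_CLUSTER_COUNT = 3

#: Relative eigenvalue floor below which a covariance is considered singular.
_SINGULAR_RATIO = 1e-10
_REG_EPS = 1e-6


class ClusterEstimationError(ValueError):
    """A genotype cluster has too few rows to form a covariance matrix."""


@dataclass
class TrainTestSplit:
    """Random partition of the known-genotype samples into training/testing."""

    training_ids: list[str]
    testing_ids: list[str]
    ratio: tuple[int, int]

    @property
    def l_a(self) -> int:
        return len(self.training_ids)


@dataclass
class FeaturedSnpStatus:
    """Training-genotype census of one featured SNP and its G1/G2 class."""

    snp_id: str
    c_as: int
    counts: tuple[int, int, int]  # training samples per genotype (AA, AB, BB)
    group: str  # "G1" or "G2"


@dataclass
class ReferenceSelection:
    """Outcome of the reference-SNP search for one G2 target."""

    target_snp_id: str
    candidates: list[str]
    distances: dict[str, float] = field(default_factory=dict)
    chosen_ref: str | None = None
    d_s: float = float("nan")


def split_known_samples(
    known: KnownGenotypeTable, ratio: tuple[int, int], seed: int
) -> TrainTestSplit:
    """Randomly allocate the known-genotype samples to training/testing.

    For ratio p:q the training size is ``ceil(n_a * p / (p + q))``; with 141
    samples this gives 94/47 at 2:1 and 71/70 at 1:1.  Membership is a
    uniform draw, reproducible under ``seed``.
    """
    p, q = int(ratio[0]), int(ratio[1])
    if p <= 0 or q <= 0:
        raise ValueError("ratio components must be positive")
    n_a = known.n_known
    if n_a < p + q:
        raise ValueError(f"need at least {p + q} known samples, have {n_a}")
    l_a = int(np.ceil(n_a * p / (p + q)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_a)
    ids = list(known.sample_ids)
    training = [ids[i] for i in perm[:l_a]]
    testing = [ids[i] for i in perm[l_a:]]
    return TrainTestSplit(training_ids=training, testing_ids=testing, ratio=(p, q))


def classify_featured_snp(snp_id: str, training_genotypes) -> FeaturedSnpStatus:
    """Classify a featured SNP as G1 or G2 from its training genotypes.

    A SNP is G1 only if all three genotypes appear among the (non-missing)
    training samples and each genotype has at least three of them; anything
    less is G2.  Missing genotypes are excluded from the counts.
    """
    g = np.asarray(training_genotypes, dtype=object)
    counts = tuple(int(np.sum(g == gt)) for gt in GENOTYPES)
    c_as = int(sum(c > 0 for c in counts))
    is_g2 = c_as < 3 or any(c < MIN_CLUSTER_COUNT for c in counts)
    return FeaturedSnpStatus(
        snp_id=snp_id, c_as=c_as, counts=counts, group="G2" if is_g2 else "G1"
    )


def project_intensity(r, g):
    """Contrast projection b = (r - g)/(r + g) of a two-channel intensity.

    Vectorised; returns NaN where r + g = 0 (undefined projection — callers
    treat such samples as missing for distance computation).
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    total = r + g
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(total > 0, (r - g) / np.where(total > 0, total, 1.0), np.nan)
    if b.ndim == 0:
        return float(b)
    return b


def candidate_reference_set(
    target_index: int, statuses: list[FeaturedSnpStatus], R: int
) -> list[str]:
    """Up to ``R`` G1 featured SNPs nearest the target in array order.

    Nearness is row-index distance in the panel (the array supplies no
    genomic coordinates); ties at equal distance go to the lower index.
    The returned list is ordered by nearness and never contains the target.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    ranked = sorted(
        (
            (abs(i - target_index), i)
            for i, st in enumerate(statuses)
            if i != target_index and st.group == "G1"
        ),
    )
    return [statuses[i].snp_id for _, i in ranked[:R]]


def projection_scale(b_columns: np.ndarray) -> np.ndarray:
    """Per-sample scale s_h for the standardised reference distance.

    ``b_columns`` is an ``(l_a, 1 + |S_R|)`` matrix of projected intensities
    of the training samples over the target SNP and its candidate set.
    s_h is the sample standard deviation of row h; rows where it is zero
    fall back to the pooled standard deviation over the whole matrix, and
    samples where even that is zero (or whose projections are undefined)
    get NaN, signalling the caller to drop them from every candidate sum
    symmetrically.
    """
    b = np.asarray(b_columns, dtype=float)
    with np.errstate(invalid="ignore"):
        s = np.nanstd(b, axis=1, ddof=1)
    finite_all = np.all(np.isfinite(b), axis=1)
    pooled = float(np.nanstd(b, ddof=1)) if np.any(np.isfinite(b)) else 0.0
    s = np.where((s == 0) & finite_all, pooled, s)
    s = np.where(finite_all & (s > 0), s, np.nan)
    return s


def select_reference_snp(
    target_b: np.ndarray,
    candidates: list[tuple[str, np.ndarray]],
    s_h: np.ndarray,
    target_snp_id: str = "",
) -> ReferenceSelection:
    """Pick the reference SNP minimising the standardised projected distance.

    d(r) = sqrt( sum_h (b_hs - b_hr)^2 / s_h^2 ) over the training samples h
    with a defined scale and projections; the candidate list must already be
    ordered by nearness so that the first minimum wins ties.
    """
    target_b = np.asarray(target_b, dtype=float)
    sel = ReferenceSelection(
        target_snp_id=target_snp_id, candidates=[c[0] for c in candidates]
    )
    if not candidates:
        return sel
    valid = np.isfinite(s_h) & np.isfinite(target_b)
    for _, b_r in candidates:
        valid &= np.isfinite(np.asarray(b_r, dtype=float))
    best_id, best_d = None, np.inf
    for snp_id, b_r in candidates:
        b_r = np.asarray(b_r, dtype=float)
        diff = (target_b[valid] - b_r[valid]) / s_h[valid]
        d = float(np.sqrt(np.sum(diff**2)))
        sel.distances[snp_id] = d
        if d < best_d:
            best_id, best_d = snp_id, d
    sel.chosen_ref = best_id
    sel.d_s = best_d
    return sel


def regularize_covariance(cov: np.ndarray) -> np.ndarray:
    """Return ``cov`` nudged to positive definiteness if near-singular.

    Adds eps * trace/2 * I (eps = 1e-6; plain eps * I when the trace is 0)
    whenever the smaller eigenvalue is below 1e-10 times the larger —
    QC replicates can be near-identical, collapsing a cluster covariance.
    """
    cov = np.asarray(cov, dtype=float).reshape(2, 2)
    cov = (cov + cov.T) / 2.0
    eig = np.linalg.eigvalsh(cov)
    if eig[0] < _SINGULAR_RATIO * max(eig[1], 0.0) or eig[0] <= 0:
        tr = float(np.trace(cov))
        bump = _REG_EPS * (tr / 2.0 if tr > 0 else 1.0)
        cov = cov + bump * np.eye(2)
    return cov


def estimate_cluster_params(
    snp_id: str,
    target_xy: np.ndarray,
    target_genotypes,
    status: FeaturedSnpStatus,
    ref_xy: np.ndarray | None = None,
    ref_genotypes=None,
    ref_snp_id: str | None = None,
) -> ClusterModel:
    """Per-genotype sample mean and covariance of the training intensities.

    G1 targets use their own training rows only; G2 targets stack the
    reference SNP's training rows of the same genotype under their own
    before taking moments, so the pooled mean divides by l_ask + l_ark and
    the pooled covariance by l_ask + l_ark - 1.  Missing training genotypes
    are excluded.  Degenerate covariances are regularised.
    """
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    tg = np.asarray(target_genotypes, dtype=object)
    use_ref = status.group == "G2"
    if use_ref:
        if ref_xy is None or ref_genotypes is None or ref_snp_id is None:
            raise ValueError("G2 target requires a reference SNP")
        ref_xy = np.asarray(ref_xy, dtype=float).reshape(-1, 2)
        rg = np.asarray(ref_genotypes, dtype=object)

    means = np.empty((3, 2))
    covs = np.empty((3, 2, 2))
    counts = np.zeros(3, dtype=int)
    ref_counts = np.zeros(3, dtype=int)
    for k, gt in enumerate(GENOTYPES):
        rows = target_xy[tg == gt]
        counts[k] = len(rows)
        if use_ref:
            ref_rows = ref_xy[rg == gt]
            ref_counts[k] = len(ref_rows)
            rows = np.vstack([rows, ref_rows]) if len(rows) else ref_rows
        if len(rows) < 2:
            raise ClusterEstimationError(
                f"cluster {gt} at SNP {snp_id!r} has {len(rows)} pooled rows; "
                "at least 2 needed for a covariance"
            )
        means[k] = rows.mean(axis=0)
        covs[k] = regularize_covariance(np.cov(rows, rowvar=False, ddof=1))
    return ClusterModel(
        snp_id=snp_id,
        means=means,
        covs=covs,
        counts=counts,
        source="G2-combined" if use_ref else "G1-direct",
        ref_snp_id=ref_snp_id if use_ref else None,
        ref_counts=ref_counts if use_ref else None,
    )
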