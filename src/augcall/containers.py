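"""Core in-memory containers for two-channel SNP-array genotype calling.

The raw data model: every SNP ``s`` and sample ``i`` carries a pair of
non-negative fluorescence intensities ``(r_is, g_is)`` — the red channel
measuring allele A and the green channel measuring allele B.  A subset of
samples (typically HapMap quality-control replicates) has known genotypes
which drive the first, cluster-estimation stage of the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Genotypes in cluster order k = 1, 2, 3.  B denotes the less common allele,
#: so cluster 1 is the major homozygote and cluster 3 the minor homozygote.
GENOTYPES: tuple[str, str, str] = ("AA", "AB", "BB")

#: Token for an unknown genotype in a known-genotype table.
MISSING = "NA"

#: Token emitted for a sample that cannot be confidently called.
NOCALL = "NoCall"


class FormatError(ValueError):
    """A malformed cell or header in one of the tabular input formats."""


class PrerequisiteError(ValueError):
    """A method prerequisite is not met (e.g. no known-genotype samples)."""


@dataclass
class IntensityPanel:
    """Two-channel raw intensities for ``n`` samples at ``S`` SNPs.

    Parameters
    ----------
    snp_ids
        Ordered SNP identifiers; array (row) order defines SNP adjacency
        used when searching for nearby reference SNPs.
    sample_ids
        Ordered sample identifiers (the cohort, set N).
    red, green
        ``(n, S)`` float arrays of non-negative intensities, red measuring
        allele A and green allele B.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    red: np.ndarray
    green: np.ndarray

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        n, s = len(self.sample_ids), len(self.snp_ids)
        if self.red.shape != (n, s) or self.green.shape != (n, s):
            raise FormatError(
                f"intensity matrices must be ({n}, {s}); "
                f"got red {self.red.shape}, green {self.green.shape}"
            )
        if len(set(self.snp_ids)) != s:
            raise FormatError("duplicate SNP identifiers in panel")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample identifiers in panel")
        for name, mat in (("red", self.red), ("green", self.green)):
            if not np.all(np.isfinite(mat)):
                raise FormatError(f"non-finite value in {name} intensities")
            if np.any(mat < 0):
                i, j = np.argwhere(mat < 0)[0]
                raise FormatError(
                    f"negative {name} intensity at sample "
                    f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc.args[0]!r} not in panel") from exc

    def snp_xy(self, snp_id: str) -> np.ndarray:
        """``(n, 2)`` stack of (red, green) intensities at one SNP."""
        j = self.snp_index(snp_id)
        return np.column_stack([self.red[:, j], self.green[:, j]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityPanel):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.red, other.red)
            and np.array_equal(self.green, other.green)
        )


@dataclass
class KnownGenotypeTable:
    """Truth genotypes for the QC subset M of the cohort.

    ``genotypes`` maps ``(sample_id, snp_id)`` to one of AA/AB/BB; pairs not
    listed (or listed as NA) are missing.  Every sample in M must match one
    unique sample in the panel's N by exact identifier equality.
    """

    sample_ids: list[str]
    genotypes: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers in known-genotype table")
        allowed = set(GENOTYPES) | {MISSING}
        for key, g in self.genotypes.items():
            if g not in allowed:
                raise FormatError(f"invalid genotype token {g!r} at {key}")

    @property
    def n_known(self) -> int:
        return len(self.sample_ids)

    def get(self, sample_id: str, snp_id: str) -> str:
        return self.genotypes.get((sample_id, snp_id), MISSING)

    def genotype_vector(self, snp_id: str, sample_ids: list[str]) -> np.ndarray:
        """Genotype tokens at one SNP for the given samples (NA if missing)."""
        return np.array([self.get(s, snp_id) for s in sample_ids], dtype=object)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnownGenotypeTable):
            return NotImplemented
        def _nonmissing(t: "KnownGenotypeTable") -> dict:
            return {k: v for k, v in t.genotypes.items() if v != MISSING}
        return self.sample_ids == other.sample_ids and _nonmissing(self) == _nonmissing(other)


@dataclass
class RunConfig:
    """Run configuration for the two-stage caller.

    Attributes
    ----------
    ratio
        Training:testing allocation ratio for the known-genotype samples,
        e.g. ``(2, 1)``.
    m
        Number of augmentation subjects simulated per SNP; must be divisible
        by 3 (equal counts per genotype cluster).
    R
        Search-window size: number of candidate reference SNPs considered
        for a target SNP lacking three well-populated clusters.
    apr_threshold
        SNP-level quality gate: the SNP is called only if its average
        posterior rate (APR) exceeds this value.
    pr_threshold
        Subject-level gate: a subject whose maximal posterior falls below
        this value receives NoCall (the "null component").
    em_tol, em_max_iter
        EM convergence controls (relative log-likelihood change, iteration cap).
    seed
        Master seed for all stochastic steps (sample split, augmentation draws).
    """

    ratio: tuple[int, int] = (2, 1)
    m: int = 3000
    R: int = 100
    apr_threshold: float = 0.85
    pr_threshold: float = 0.85
    em_tol: float = 1e-8
    em_max_iter: int = 500
    seed: int = 20151203

    def __post_init__(self) -> None:
        p, q = self.ratio
        if p <= 0 or q <= 0:
            raise ValueError("allocation ratio components must be positive")
        self.ratio = (int(p), int(q))
        if self.m < 0 or self.m % 3 != 0:
            raise ValueError(f"m must be a non-negative multiple of 3, got {self.m}")
        if self.R < 1:
            raise ValueError("reference search window R must be >= 1")
        for name in ("apr_threshold", "pr_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")
        if self.em_max_iter < 1:
            raise ValueError("em_max_iter must be positive")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        if "ratio" in kwargs and not isinstance(kwargs["ratio"], tuple):
            r = kwargs["ratio"]
            if isinstance(r, str):
                p, q = r.split(":")
            else:
                p, q = r
            kwargs["ratio"] = (int(p), int(q))
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        return {
            "ratio": f"{self.ratio[0]}:{self.ratio[1]}",
            "m": self.m,
            "R": self.R,
            "apr_threshold": self.apr_threshold,
            "pr_threshold": self.pr_threshold,
            "em_tol": self.em_tol,
            "em_max_iter": self.em_max_iter,
            "seed": self.seed,
        }


@dataclass
class ClusterModel:
    """Per-SNP three-cluster model estimated from training samples.

    ``means[k]`` and ``covs[k]`` are the (2,) mean and (2, 2) covariance of
    genotype cluster k (0=AA, 1=AB, 2=BB) in (red, green) intensity space.
    ``source`` records whether the clusters came from the SNP's own training
    rows (``G1-direct``) or were pooled with a borrowed reference SNP
    (``G2-combined``), in which case ``ref_snp_id`` names the reference.
    """

    snp_id: str
    means: np.ndarray
    covs: np.ndarray
    counts: np.ndarray
    source: str
    ref_snp_id: str | None = None
    ref_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(3, 2)
        self.covs = np.asarray(self.covs, dtype=float).reshape(3, 2, 2)
        self.counts = np.asarray(self.counts, dtype=int).reshape(3)
        if self.source not in ("G1-direct", "G2-combined"):
            raise ValueError(f"unknown cluster source {self.source!r}")
        if self.source == "G2-combined" and self.ref_snp_id is None:
            raise ValueError("G2-combined model requires a reference SNP id")
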