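"""Evaluation statistics for genotype call sets.

Call rate, concordance/accuracy, minor-allele frequency, MAF-stratified
summaries against a truth table, and a 1-df chi-square Hardy-Weinberg
equilibrium test — the standard QC battery for a genotype caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GENOTYPES, KnownGenotypeTable


@dataclass
class GenotypeCounts:
    """Genotype census at one SNP (called samples plus NoCalls)."""

    n_aa: int
    n_ab: int
    n_bb: int
    n_nocall: int = 0

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ab", "n_bb", "n_nocall"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def total(self) -> int:
        return self.n_called + self.n_nocall

    @classmethod
    def from_calls(cls, genotypes: Iterable[str]) -> "GenotypeCounts":
        g = list(genotypes)
        return cls(
            n_aa=g.count("AA"),
            n_ab=g.count("AB"),
            n_bb=g.count("BB"),
            n_nocall=len(g) - g.count("AA") - g.count("AB") - g.count("BB"),
        )


@dataclass
class HweResult:
    """1-df goodness-of-fit test of Hardy-Weinberg proportions."""

    chi_square: float
    p_value: float
    p_hat: float  # estimated frequency of allele A
    df: int = 1


def call_rate(counts: GenotypeCounts) -> float:
    """Fraction of attempted genotypes that received a call."""
    if counts.total == 0:
        raise ValueError("no genotypes attempted")
    return counts.n_called / counts.total


def concordance(calls_a: Sequence[str], calls_b: Sequence[str]) -> float:
    """Agreement fraction over positions where both lists are called.

    Accuracy is concordance against a truth list.  Returns NaN when no
    position is jointly called.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call lists must have equal length")
    called = set(GENOTYPES)
    joint = [(a, b) for a, b in zip(calls_a, calls_b) if a in called and b in called]
    if not joint:
        return float("nan")
    return sum(a == b for a, b in joint) / len(joint)


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """MAF from called genotypes; invariant under swapping allele labels."""
    n = counts.n_called
    if n == 0:
        raise ValueError("no called genotypes")
    freq_b = (counts.n_ab + 2 * counts.n_bb) / (2 * n)
    return min(freq_b, 1.0 - freq_b)


def hwe_chi_square(counts: GenotypeCounts) -> HweResult:
    """Chi-square test of Hardy-Weinberg proportions with estimated allele frequency.

    Expected counts are (n p^2, 2 n p (1-p), n (1-p)^2) with p estimated from
    the data; one degree of freedom.  Cells with zero expectation contribute
    nothing, and a monomorphic SNP is in exact equilibrium by convention.
    """
    n = counts.n_called
    if n == 0:
        raise ValueError("no called genotypes")
    p_hat = (2 * counts.n_aa + counts.n_ab) / (2 * n)
    expected = np.array(
        [n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2]
    )
    observed = np.array([counts.n_aa, counts.n_ab, counts.n_bb], dtype=float)
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi_square=chi2, p_value=p_value, p_hat=p_hat)


def _truth_maf(truth: KnownGenotypeTable, snp_id: str) -> float:
    g = truth.genotype_vector(snp_id, truth.sample_ids)
    counts = GenotypeCounts.from_calls(g)
    if counts.n_called == 0:
        return float("nan")
    return minor_allele_frequency(counts)


def maf_stratified_report(
    calls: pd.DataFrame,
    truth: KnownGenotypeTable,
    bins: Sequence[float] = (0.1, 0.05, 0.01),
) -> pd.DataFrame:
    """Per-MAF-bin SNP counts, call rates and accuracies against truth.

    ``calls`` is a long table with columns sample_id, snp_id, genotype.  The
    MAF of each SNP comes from the truth genotypes of all truth-bearing
    samples; each bin collects SNPs with MAF strictly below its cutoff
    (default cutoffs 0.1, 0.05, 0.01).  Accuracy is computed over jointly
    called (call, truth) pairs; empty bins report count 0 and NaN metrics.
    """
    bins = sorted(bins, reverse=True)
    snp_ids = list(dict.fromkeys(calls["snp_id"]))
    maf = {s: _truth_maf(truth, s) for s in snp_ids}
    truth_set = set(truth.sample_ids)
    rows = []
    for cutoff in bins:
        members = [s for s in snp_ids if np.isfinite(maf[s]) and maf[s] < cutoff]
        sub = calls[calls["snp_id"].isin(members)]
        if len(sub) == 0:
            rows.append(
                {
                    "maf_below": cutoff,
                    "n_snps": 0,
                    "call_rate": float("nan"),
                    "accuracy": float("nan"),
                }
            )
            continue
        counts = GenotypeCounts.from_calls(sub["genotype"])
        tr = sub[sub["sample_id"].isin(truth_set)]
        truth_calls = [truth.get(s, p) for s, p in zip(tr["sample_id"], tr["snp_id"])]
        rows.append(
            {
                "maf_below": cutoff,
                "n_snps": len(members),
                "call_rate": call_rate(counts),
                "accuracy": concordance(list(tr["genotype"]), truth_calls),
            }
        )
    return pd.DataFrame(rows)


def hwe_report(
    calls: pd.DataFrame,
    alpha: float = 1e-4,
    populations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-SNP (optionally per-population) HWE chi-square test of the calls.

    ``populations`` maps sample_id to a population label; when given, the
    test runs within each population separately (the standard guard against
    spurious HWE failure from population structure).  A SNP row is flagged
    when its p-value falls below ``alpha``.
    """
    frames = []
    if populations:
        tagged = calls.assign(
            population=[populations.get(s, "all") for s in calls["sample_id"]]
        )
        groups = tagged.groupby(["population", "snp_id"], sort=False)
    else:
        groups = calls.assign(population="all").groupby(
            ["population", "snp_id"], sort=False
        )
    for (pop, snp_id), sub in groups:
        counts = GenotypeCounts.from_calls(sub["genotype"])
        if counts.n_called == 0:
            frames.append(
                {
                    "population": pop,
                    "snp_id": snp_id,
                    "chi_square": float("nan"),
                    "p_value": float("nan"),
                    "hwe_fail": False,
                }
            )
            continue
        res = hwe_chi_square(counts)
        frames.append(
            {
                "population": pop,
                "snp_id": snp_id,
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "hwe_fail": bool(res.p_value < alpha),
            }
        )
    return pd.DataFrame(frames)
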