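"""Synthetic two-channel SNP-array panels with known ground truth.

Each SNP is a three-cluster bivariate Gaussian in (red, green) intensity
space: genotypes are drawn under Hardy-Weinberg equilibrium at a
configurable minor-allele frequency and the intensity pair is drawn from
that genotype's cluster.  Per-SNP multiplicative jitter of the cluster
means emulates probe-to-probe variation — the feature that motivates
reference-SNP borrowing.  A configurable subset of samples carries known
genotypes (with optional missingness), mirroring HapMap QC replicates.

The generator emulates only what the calling model assumes.  It does not
model scanner artifacts, bead-level replication, batch effects, or
intensity-dependent noise, so results on these panels bound, but do not
certify, behaviour on real array data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GENOTYPES, MISSING, IntensityPanel, KnownGenotypeTable


@dataclass
class ClusterGeometry:
    """Base cluster means and spread in (red, green) space.

    Defaults put AA at (4000, 500), AB at (2250, 2250) and BB at (500, 4000)
    with diagonal covariances of sd = 200 * scale, so the projected contrast
    b = (r - g)/(r + g) sits near +0.78 / 0 / -0.78 — typical two-channel
    array geometry.
    """

    means: np.ndarray = field(
        default_factory=lambda: np.array(
            [[4000.0, 500.0], [2250.0, 2250.0], [500.0, 4000.0]]
        )
    )
    sd: float = 200.0
    scale: float = 1.0

    def covariances(self) -> np.ndarray:
        v = (self.sd * self.scale) ** 2
        return np.array([np.eye(2) * v for _ in range(3)])


@dataclass
class SimulationConfig:
    """Parameters of one synthetic panel.

    ``maf_spec`` is either a single MAF applied to every SNP, or a sequence
    of per-SNP MAFs (each in [0, 0.5]).  ``snp_jitter`` is the log-scale sd
    of the multiplicative lognormal perturbation applied independently to
    each cluster-mean coordinate per SNP.  ``missing_known_rate`` is the
    fraction of known-genotype entries blanked to NA.
    """

    n_samples: int
    n_snps: int
    n_known: int
    maf_spec: float | np.ndarray = 0.2
    geometry: ClusterGeometry = field(default_factory=ClusterGeometry)
    snp_jitter: float = 0.05
    missing_known_rate: float = 0.02
    seed: int = 20151203

    def __post_init__(self) -> None:
        if self.n_known > self.n_samples:
            raise ValueError("n_known cannot exceed n_samples")
        if not 0.0 <= self.missing_known_rate < 1.0:
            raise ValueError("missing_known_rate must lie in [0, 1)")
        mafs = self.per_snp_maf()
        if np.any(mafs < 0) or np.any(mafs > 0.5):
            raise ValueError("MAF values must lie in [0, 0.5]")

    def per_snp_maf(self) -> np.ndarray:
        mafs = np.asarray(self.maf_spec, dtype=float)
        if mafs.ndim == 0:
            mafs = np.full(self.n_snps, float(mafs))
        if len(mafs) != self.n_snps:
            raise ValueError("per-SNP maf_spec length must equal n_snps")
        return mafs


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated panel."""

    genotypes: np.ndarray  # (n_samples, n_snps) of genotype tokens
    cluster_means: np.ndarray  # (n_snps, 3, 2)
    cluster_covs: np.ndarray  # (n_snps, 3, 2, 2)
    maf: np.ndarray  # (n_snps,)
    known_sample_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def genotype(self, sample_id: str, snp_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        j = self.snp_ids.index(snp_id)
        return str(self.genotypes[i, j])

    def as_known_table(self) -> KnownGenotypeTable:
        """Full truth as a known-genotype table over all samples."""
        mapping = {
            (s, p): str(self.genotypes[i, j])
            for i, s in enumerate(self.sample_ids)
            for j, p in enumerate(self.snp_ids)
        }
        return KnownGenotypeTable(sample_ids=list(self.sample_ids), genotypes=mapping)


def _hwe_probs(maf: float) -> np.ndarray:
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def generate_panel(
    config: SimulationConfig,
) -> tuple[IntensityPanel, KnownGenotypeTable, SyntheticTruth]:
    """Generate a panel, its known-genotype QC table and the full truth.

    For each SNP the genotype of every sample is multinomial under HWE at
    that SNP's MAF; the intensity pair is bivariate normal around the SNP's
    jittered cluster mean, truncated at zero (intensities are non-negative).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_samples, config.n_snps
    mafs = config.per_snp_maf()
    base_means = np.asarray(config.geometry.means, dtype=float)
    covs = config.geometry.covariances()

    sample_ids = [f"S{i:04d}" for i in range(n)]
    snp_ids = [f"snp{j:04d}" for j in range(s)]

    genotypes = np.empty((n, s), dtype=object)
    red = np.empty((n, s))
    green = np.empty((n, s))
    true_means = np.empty((s, 3, 2))
    true_covs = np.empty((s, 3, 2, 2))
    for j in range(s):
        jitter = rng.lognormal(mean=0.0, sigma=config.snp_jitter, size=(3, 2))
        means_j = base_means * jitter
        true_means[j] = means_j
        true_covs[j] = covs
        g_idx = rng.choice(3, size=n, p=_hwe_probs(mafs[j]))
        genotypes[:, j] = np.array(GENOTYPES, dtype=object)[g_idx]
        xy = np.empty((n, 2))
        for k in range(3):
            members = g_idx == k
            if members.any():
                xy[members] = rng.multivariate_normal(
                    means_j[k], covs[k], size=int(members.sum())
                )
        np.clip(xy, 0.0, None, out=xy)
        red[:, j] = xy[:, 0]
        green[:, j] = xy[:, 1]

    panel = IntensityPanel(
        snp_ids=snp_ids, sample_ids=sample_ids, red=red, green=green
    )

    known_ids = sample_ids[: config.n_known]
    known_map: dict[tuple[str, str], str] = {}
    for i, sid in enumerate(known_ids):
        for j, pid in enumerate(snp_ids):
            if config.missing_known_rate and rng.random() < config.missing_known_rate:
                continue
            known_map[(sid, pid)] = str(genotypes[i, j])
    known = KnownGenotypeTable(sample_ids=list(known_ids), genotypes=known_map)

    truth = SyntheticTruth(
        genotypes=genotypes,
        cluster_means=true_means,
        cluster_covs=true_covs,
        maf=mafs,
        known_sample_ids=list(known_ids),
        sample_ids=sample_ids,
        snp_ids=snp_ids,
    )
    return panel, known, truth


def make_rare_panel_fixture(
    n_samples: int,
    n_rare: int,
    maf: float,
    seed: int,
    n_known: int = 60,
    n_backbone: int | None = None,
    backbone_maf: float = 0.5,
    **config_kwargs,
) -> tuple[IntensityPanel, KnownGenotypeTable, SyntheticTruth]:
    """Panel of rare SNPs interleaved with a common-SNP reference backbone.

    At MAF <= 0.01 and a few hundred samples the expected minor-homozygote
    count is below one (n * maf^2), so rare SNPs show three, two or one
    observed cluster depending on the genotype draw.  The backbone SNPs at
    MAF 0.5 almost surely have three well-populated training clusters when
    n_known >= 60, guaranteeing that references exist nearby.
    """
    if maf > 0.01:
        raise ValueError("rare fixture requires maf <= 0.01")
    if n_rare < 1:
        raise ValueError("need at least one rare SNP")
    if n_backbone is None:
        n_backbone = max(4, n_rare)
    # Interleave: backbone, rare, backbone, rare, ... so every rare target
    # has a G1 neighbour within a window of 2.
    maf_list: list[float] = []
    rare_flags: list[bool] = []
    r_left, b_left = n_rare, n_backbone
    while r_left or b_left:
        if b_left:
            maf_list.append(backbone_maf)
            rare_flags.append(False)
            b_left -= 1
        if r_left:
            maf_list.append(maf)
            rare_flags.append(True)
            r_left -= 1
    cfg = SimulationConfig(
        n_samples=n_samples,
        n_snps=len(maf_list),
        n_known=n_known,
        maf_spec=np.array(maf_list),
        seed=seed,
        **config_kwargs,
    )
    return generate_panel(cfg)
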