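"""Stage II: augmented-data Gaussian-mixture genotype calling.

For each SNP, m additional subjects are simulated from the Stage-I cluster
model (m/3 per genotype cluster, so the augmentation never changes which
observed homozygote cluster is the larger one), stacked under the observed
cohort, and a three-component bivariate Gaussian mixture is fitted by EM.
Subjects are assigned to their highest-posterior component; the posterior
rate (PR) of a subject is that posterior, and the average posterior rate
(APR) over the augmented subjects gates SNP quality.  Subjects whose best
posterior is too diffuse fall into a null component and receive NoCall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import stage1
from .containers import (
    GENOTYPES,
    NOCALL,
    ClusterModel,
    IntensityPanel,
    KnownGenotypeTable,
    PrerequisiteError,
    RunConfig,
)

_COLLAPSE_WEIGHT = 1e-8


class LabelingError(ValueError):
    """Component means cannot be ordered on the contrast coordinate."""


@dataclass
class GmmFit:
    """Converged (or flagged) three-component bivariate mixture for one SNP."""

    snp_id: str
    weights: np.ndarray  # (3,) mixing proportions on the simplex
    means: np.ndarray  # (3, 2)
    covs: np.ndarray  # (3, 2, 2)
    resp: np.ndarray  # (n*, 3) responsibilities, rows sum to 1
    log_likelihood: list[float]
    converged: bool
    collapsed: bool = False


@dataclass
class CallSet:
    """Genotype calls for the observed cohort plus a per-SNP quality report.

    ``calls`` has one row per (sample, SNP) with columns sample_id, snp_id,
    genotype (AA/AB/BB/NoCall) and PR; ``snp_report`` has one row per SNP
    with group, reference, APR (augmented and observed-only), pass flag,
    convergence flag and the fitted component means/weights.  Simulated
    augmentation subjects never appear in either table.
    """

    calls: pd.DataFrame
    snp_report: pd.DataFrame


def simulate_augmented_samples(
    model: ClusterModel, m: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw m augmentation subjects, m/3 per genotype cluster.

    Returns the ``(m, 2)`` intensity block and the ``(m,)`` integer array of
    component-of-origin labels (0=AA, 1=AB, 2=BB).  Deterministic under
    ``seed`` (an int, SeedSequence or Generator).
    """
    if m < 0 or m % 3 != 0:
        raise ValueError(f"m must be a non-negative multiple of 3, got {m}")
    rng = np.random.default_rng(seed)
    if m == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    per = m // 3
    blocks, labels = [], []
    for k in range(3):
        cov = stage1.regularize_covariance(model.covs[k])
        blocks.append(rng.multivariate_normal(model.means[k], cov, size=per))
        labels.append(np.full(per, k, dtype=int))
    return np.vstack(blocks), np.concatenate(labels)


def _log_bivariate_normal(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log-density of a bivariate normal at the rows of ``x`` (Cholesky form)."""
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (maha + logdet + 2.0 * np.log(2.0 * np.pi))


def _e_step(
    x: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> tuple[np.ndarray, float]:
    """Responsibilities and total log-likelihood at the current parameters."""
    logp = np.column_stack(
        [
            np.log(weights[k]) + _log_bivariate_normal(x, means[k], covs[k])
            for k in range(3)
        ]
    )
    norm = logsumexp(logp, axis=1)
    resp = np.exp(logp - norm[:, None])
    return resp, float(np.sum(norm))


def em_fit_gmm(
    data: np.ndarray,
    init: ClusterModel,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GmmFit:
    """Fit the three-component bivariate GMM to the augmented data by EM.

    Initialised at the Stage-I cluster means/covariances with uniform
    weights.  Each E-step evaluates the posterior membership probabilities;
    the M-step recomputes the responsibility-weighted means, covariances and
    mixing proportions.  Iteration stops when the relative log-likelihood
    change drops below ``tol``.  If a component's effective weight vanishes
    (no data near it) the fit is flagged collapsed and returned unconverged.
    """
    x = np.asarray(data, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensity in augmented data")
    n_star = len(x)
    weights = np.full(3, 1.0 / 3.0)
    means = init.means.copy()
    covs = np.array([stage1.regularize_covariance(c) for c in init.covs])

    trace: list[float] = []
    resp = np.full((n_star, 3), 1.0 / 3.0)
    converged = False
    collapsed = False
    ll_prev = -np.inf
    for _ in range(max_iter):
        resp, ll = _e_step(x, weights, means, covs)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        if nk.min() < _COLLAPSE_WEIGHT:
            collapsed = True
            break
        weights = nk / n_star
        means = (resp.T @ x) / nk[:, None]
        for k in range(3):
            diff = x - means[k]
            covs[k] = stage1.regularize_covariance(
                (resp[:, k, None] * diff).T @ diff / nk[k]
            )
    return GmmFit(
        snp_id=init.snp_id,
        weights=weights,
        means=means,
        covs=covs,
        resp=resp,
        log_likelihood=trace,
        converged=converged,
        collapsed=collapsed,
    )


def map_components_to_genotypes(fit: GmmFit) -> tuple[dict[int, str], bool]:
    """Order the fitted components on the contrast coordinate and label them.

    The component with the largest b(mu) = (mu_r - mu_g)/(mu_r + mu_g) is AA
    (allele A on the red channel), the middle one AB, the smallest BB.
    Returns the label map and a flag that is True when two components tied
    exactly (broken toward the lower component index).
    """
    sums = fit.means.sum(axis=1)
    if np.sum(sums <= 0) >= 2:
        raise LabelingError("two component means with zero total intensity")
    b = np.where(sums > 0, (fit.means[:, 0] - fit.means[:, 1]) / np.where(sums > 0, sums, 1.0), 0.0)
    order = sorted(range(3), key=lambda k: (-b[k], k))
    tie = len(np.unique(b)) < 3
    return {comp: GENOTYPES[rank] for rank, comp in enumerate(order)}, tie


def posterior_rates(fit: GmmFit, n: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-subject posterior rates and the SNP-level average posterior rate.

    Each of the n* augmented subjects is hard-assigned to its highest-
    posterior component (ties toward the lower index); its PR is that
    posterior.  The APR averages PR over all augmented subjects; the
    observed-only APR averages over the first ``n`` (observed) rows.
    """
    assigned = np.argmax(fit.resp, axis=1)
    pr = fit.resp[np.arange(len(assigned)), assigned]
    apr_augmented = float(pr.mean()) if len(pr) else float("nan")
    apr_observed = float(pr[:n].mean()) if n else float("nan")
    return assigned, pr, apr_augmented, apr_observed


def assign_genotypes(
    fit: GmmFit,
    labels: dict[int, str],
    apr_threshold: float,
    pr_threshold: float,
    n: int,
) -> tuple[list[str], np.ndarray, float, float, bool]:
    """Turn a fitted mixture into genotype calls for the observed subjects.

    The SNP passes only if the augmented-data APR exceeds ``apr_threshold``;
    on failure every observed subject is NoCall.  On a passing SNP each
    observed subject gets the genotype of its assigned component unless its
    PR falls below ``pr_threshold`` (the null component), in which case it
    alone is NoCall.  Simulated subjects are never emitted.
    """
    assigned, pr, apr_aug, apr_obs = posterior_rates(fit, n)
    snp_pass = bool(apr_aug > apr_threshold)
    genotypes: list[str] = []
    for w in range(n):
        if not snp_pass or pr[w] < pr_threshold:
            genotypes.append(NOCALL)
        else:
            genotypes.append(labels[assigned[w]])
    return genotypes, pr[:n], apr_aug, apr_obs, snp_pass


def _failed_snp_rows(panel: IntensityPanel, snp_id: str, group: str, reason: str):
    calls = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "snp_id": snp_id,
            "genotype": NOCALL,
            "PR": np.nan,
        }
    )
    report = {
        "snp_id": snp_id,
        "group": group,
        "ref_snp_id": "",
        "m": 0,
        "apr_augmented": np.nan,
        "apr_observed": np.nan,
        "snp_pass": False,
        "converged": False,
        "note": reason,
    }
    return calls, report


def call_panel(
    panel: IntensityPanel, known: KnownGenotypeTable, config: RunConfig
) -> CallSet:
    """Run the full two-stage pipeline over a panel.

    Orchestrates: training/testing split of the known-genotype samples,
    G1/G2 classification per SNP, reference-SNP selection for G2 targets,
    cluster estimation, augmentation simulation, EM fitting, PR/APR scoring
    and genotype assignment.  Fully deterministic under ``config.seed``.
    """
    if known.n_known == 0 or not any(
        g != "NA" for g in known.genotypes.values()
    ):
        raise PrerequisiteError(
            "the method requires samples with known genotypes; the known-"
            "genotype table is empty"
        )
    split = stage1.split_known_samples(known, config.ratio, config.seed)
    train_ids = [s for s in split.training_ids]
    train_rows = panel.sample_indices(train_ids)

    statuses = [
        classify_snp_from_table(known, snp_id, train_ids)
        for snp_id in panel.snp_ids
    ]

    # Projected training profile for every SNP, used by reference selection.
    b_train = stage1.project_intensity(
        panel.red[train_rows, :], panel.green[train_rows, :]
    )

    snp_seeds = np.random.SeedSequence(config.seed).spawn(panel.n_snps)
    call_frames: list[pd.DataFrame] = []
    report_rows: list[dict] = []
    n = panel.n_samples
    snp_pos = {st.snp_id: i for i, st in enumerate(statuses)}
    for j, snp_id in enumerate(panel.snp_ids):
        status = statuses[j]
        train_xy = panel.snp_xy(snp_id)[train_rows]
        train_g = known.genotype_vector(snp_id, train_ids)

        ref_id = None
        try:
            if status.group == "G1":
                model = stage1.estimate_cluster_params(
                    snp_id, train_xy, train_g, status
                )
            else:
                cand_ids = stage1.candidate_reference_set(j, statuses, config.R)
                if not cand_ids:
                    raise stage1.ClusterEstimationError("no G1 reference available")
                cand_cols = [snp_pos[c] for c in cand_ids]
                s_h = stage1.projection_scale(b_train[:, [j] + cand_cols])
                selection = stage1.select_reference_snp(
                    b_train[:, j],
                    [(c, b_train[:, snp_pos[c]]) for c in cand_ids],
                    s_h,
                    target_snp_id=snp_id,
                )
                ref_id = selection.chosen_ref
                if ref_id is None:
                    raise stage1.ClusterEstimationError("reference selection failed")
                ref_xy = panel.snp_xy(ref_id)[train_rows]
                ref_g = known.genotype_vector(ref_id, train_ids)
                model = stage1.estimate_cluster_params(
                    snp_id, train_xy, train_g, status, ref_xy, ref_g, ref_id
                )
        except stage1.ClusterEstimationError as exc:
            calls, report = _failed_snp_rows(panel, snp_id, status.group, str(exc))
            call_frames.append(calls)
            report_rows.append(report)
            continue

        sim_xy, _ = simulate_augmented_samples(model, config.m, snp_seeds[j])
        observed = panel.snp_xy(snp_id)
        augmented = np.vstack([observed, sim_xy]) if len(sim_xy) else observed
        fit = em_fit_gmm(augmented, model, config.em_tol, config.em_max_iter)
        try:
            labels, _tie = map_components_to_genotypes(fit)
        except LabelingError as exc:
            calls, report = _failed_snp_rows(panel, snp_id, status.group, str(exc))
            call_frames.append(calls)
            report_rows.append(report)
            continue
        genotypes, pr, apr_aug, apr_obs, snp_pass = assign_genotypes(
            fit, labels, config.apr_threshold, config.pr_threshold, n
        )
        call_frames.append(
            pd.DataFrame(
                {
                    "sample_id": panel.sample_ids,
                    "snp_id": snp_id,
                    "genotype": genotypes,
                    "PR": pr,
                }
            )
        )
        row = {
            "snp_id": snp_id,
            "group": status.group,
            "ref_snp_id": ref_id or "",
            "m": config.m,
            "apr_augmented": apr_aug,
            "apr_observed": apr_obs,
            "snp_pass": snp_pass,
            "converged": fit.converged,
            "note": "collapsed" if fit.collapsed else "",
        }
        for k, gt in enumerate(GENOTYPES):
            row[f"pi_{gt}"] = float(fit.weights[k])
            row[f"mu_{gt}_r"] = float(fit.means[k, 0])
            row[f"mu_{gt}_g"] = float(fit.means[k, 1])
        report_rows.append(row)

    calls = pd.concat(call_frames, ignore_index=True)
    report = pd.DataFrame(report_rows)
    return CallSet(calls=calls, snp_report=report)


def classify_snp_from_table(
    known: KnownGenotypeTable, snp_id: str, training_ids: list[str]
):
    """Featured-SNP classification straight from a known-genotype table."""
    return stage1.classify_featured_snp(
        snp_id, known.genotype_vector(snp_id, training_ids)
    )
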