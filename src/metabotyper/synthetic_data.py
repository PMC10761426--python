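"""Synthetic five-platform metabolomics studies with known ground truth.

The generator emulates the design of a multiplatform untargeted serum
metabolomics study of ~100 children: a small number of latent metabolic
factors, each expressed as a block of co-regulated features on one analytical
platform; three sample clusters ("metabotypes") that differ in their latent
factor means; pooled QC samples injected along the sequence; a smooth
multiplicative injection-order drift; completely-at-random missing values;
and one spiked internal-standard channel per platform.

Every downstream stage (preprocessing, factor-analysis integration,
metabotype clustering) can therefore be tested against a known answer
without any external download.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (FeatureMatrix, StudyBundle, read_feature_matrix,
                         read_metadata, write_feature_matrix, write_metadata)


#: noise_sd at which a block's standardized loading equals block_loading_std
REFERENCE_NOISE_SD = 0.25


@dataclasses.dataclass
class FactorBlock:
    """A block of platform features loading on one latent factor."""

    factor: int          # 0-based factor index
    n_vars: int          # number of features in the block
    loading: float = 0.8


@dataclasses.dataclass
class PlatformSpec:
    platform_id: str
    n_features: int
    blocks: tuple[FactorBlock, ...] = ()
    drift_a: float = 0.3   # sinusoidal drift amplitude
    drift_b: float = 0.2   # linear drift amplitude
    # non-block ("diffuse") features: untargeted features outside the clean
    # chemical-class blocks are not white noise.  They (a) come in large
    # redundancy families (adducts, isotopologues, in-source fragments and
    # co-regulated species of one compound class, within-family |r| ~ 0.94)
    # that the intra-matrix correlation filter collapses to one
    # representative, and (b) cross-load on ``crossload_k`` latent factors —
    # the platform's own factors first, padded with random foreign factors —
    # at standardized loading ``crossload_loading`` each (random signs),
    # i.e. they show the double saturation the retention rule is designed
    # to discard.
    crossload_k: int = 2
    crossload_loading: float = 0.6
    diffuse_scale: float = 2.0    # total sd of a diffuse feature / noise_sd
    family_size: int = 35
    family_r: float = 0.97        # within-family correlation target

    def __post_init__(self) -> None:
        used = sum(b.n_vars for b in self.blocks)
        if used > self.n_features:
            raise ValueError(f"{self.platform_id}: blocks exceed feature count")
        factors = [b.factor for b in self.blocks]
        if len(set(factors)) != len(factors):
            raise ValueError(f"{self.platform_id}: blocks must load distinct factors")


@dataclasses.dataclass
class GroundTruth:
    """Full parameterization of one simulated study."""

    n_factors: int
    cluster_sizes: tuple[int, ...]
    cluster_factor_means: np.ndarray        # clusters x factors
    platform_specs: tuple[PlatformSpec, ...]
    noise_sd: float = 0.25
    block_loading_std: float = 0.90
    cluster_spread: float = 0.45
    missing_rate: float = 0.02
    n_qc: int | None = None                 # default: 1 per 10 study samples, min 5
    qc_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_factor_means = np.asarray(self.cluster_factor_means, dtype=float)
        if self.cluster_factor_means.shape != (len(self.cluster_sizes), self.n_factors):
            raise ValueError("cluster_factor_means must be clusters x factors")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for spec in self.platform_specs:
            for b in spec.blocks:
                if not 0 <= b.factor < self.n_factors:
                    raise ValueError("block factor index out of range")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def between_cov(self) -> np.ndarray:
        """Between-cluster covariance of the latent factors."""
        w = np.asarray(self.cluster_sizes, dtype=float)
        w = w / w.sum()
        dm = self.cluster_factor_means - w @ self.cluster_factor_means
        return (dm * w[:, None]).T @ dm

    def within_cov(self) -> np.ndarray:
        """Within-cluster covariance of the latent factor scores.

        Factor scores of a varimax (orthogonal) factor model are close to
        uncorrelated over the whole study, so the within-cluster covariance
        partially cancels the between-cluster covariance induced by the
        metabotype means: ``W = diag(s^2 (1 - b_ff)) - gamma * offdiag(B)``
        with the largest ``gamma`` in [0, 1] keeping W positive definite.
        ``cluster_spread`` (s < 1) reflects that observed metabotypes are
        tighter than a unit-variance Gaussian mixture (see the methods
        note for the calibration).
        """
        B = self.between_cov()
        b = np.clip(np.diag(B), 0.0, 0.95)
        v = (self.cluster_spread ** 2) * (1.0 - b)
        off = B - np.diag(np.diag(B))
        gamma = 1.0
        for _ in range(40):
            W = np.diag(v) - gamma * off
            if np.linalg.eigvalsh(W).min() >= 0.02:
                break
            gamma *= 0.9
        else:
            gamma = 0.0
            W = np.diag(v)
        return W

    def factor_scales(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-factor (within-cluster sd, marginal sd) of the latent scores."""
        W = self.within_cov()
        between = np.diag(self.between_cov())
        within_sd = np.sqrt(np.diag(W))
        marginal_sd = np.sqrt(np.diag(W) + between)
        return within_sd, marginal_sd

    @property
    def n_study(self) -> int:
        return int(sum(self.cluster_sizes))

    def qc_count(self) -> int:
        if self.n_qc is not None:
            return self.n_qc
        return max(5, self.n_study // 10)

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "cluster_sizes": list(self.cluster_sizes),
            "cluster_factor_means": self.cluster_factor_means.tolist(),
            "platforms": [
                {
                    "platform_id": s.platform_id,
                    "n_features": s.n_features,
                    "blocks": [dataclasses.asdict(b) for b in s.blocks],
                    "drift_a": s.drift_a,
                    "drift_b": s.drift_b,
                }
                for s in self.platform_specs
            ],
            "noise_sd": self.noise_sd,
            "missing_rate": self.missing_rate,
            "n_qc": self.qc_count(),
            "qc_noise_sd": self.qc_noise_sd,
            "seed": self.seed,
        }


#: cluster-wise latent factor means of the three metabotypes (clusters x factors)
DEFAULT_CLUSTER_FACTOR_MEANS = np.array([
    # F1      F2      F3     F4      F5      F6
    [-0.06, -0.30, -0.33,  0.05, -0.15, -0.08],   # metabotype 1 (n=74)
    [-0.03,  0.01,  2.10, -0.13, -0.29, -0.59],   # metabotype 2 (n=10)
    [ 0.32,  1.38,  0.20, -0.16,  0.88,  0.75],   # metabotype 3 (n=16)
])


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The default study conditions.

    Six latent factors; three metabotypes of sizes (74, 10, 16) whose factor
    means follow the three-cluster pattern above; five platforms with
    (345, 170, 63, 242, 91) features.  Each factor loads one block of one
    platform's features (factor membership tracks the analytical technique):
    three lipid blocks of 20, 13 and 10 features on LC-MS(+), one
    11-feature free-fatty-acid-like block on LC-MS(-), one 12-feature
    amino-acid-like block on GC-MS and one 5-feature block on CE-MS(+);
    CE-MS(-) carries no latent block.  Block loading 0.8 with noise_sd 0.5
    gives standardized within-block loadings of roughly 0.7-0.9.
    """
    platforms = (
        PlatformSpec("lcms_pos", 345, (
            FactorBlock(0, 20), FactorBlock(1, 13), FactorBlock(4, 10))),
        PlatformSpec("lcms_neg", 170, (FactorBlock(3, 11),)),
        PlatformSpec("gcms", 63, (FactorBlock(2, 12),)),
        PlatformSpec("cems_pos", 242, (FactorBlock(5, 5),)),
        PlatformSpec("cems_neg", 91, ()),
    )
    return GroundTruth(
        n_factors=6,
        cluster_sizes=(74, 10, 16),
        cluster_factor_means=DEFAULT_CLUSTER_FACTOR_MEANS.copy(),
        platform_specs=platforms,
        seed=seed,
    )


def drift_multiplier(order: np.ndarray, last_order: int,
                     a: float, b: float) -> np.ndarray:
    """Smooth multiplicative injection-order trend 1 + a sin(pi o/O) + b o/O."""
    o = np.asarray(order, dtype=float)
    return 1.0 + a * np.sin(np.pi * o / last_order) + b * (o / last_order)


def _injection_layout(n_study: int, n_qc: int, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Injection orders: blanks at the ends, QCs spread evenly, study shuffled."""
    n_blank = 2
    total = n_study + n_qc + n_blank
    orders = np.arange(1, total + 1)
    blank_orders = np.array([orders[0], orders[-1]])
    inner = orders[1:-1]
    qc_pos = np.unique(np.linspace(0, len(inner) - 1, n_qc).round().astype(int))
    if len(qc_pos) < n_qc:  # rounding collisions in tiny studies
        unused = np.setdiff1d(np.arange(len(inner)), qc_pos)
        qc_pos = np.sort(np.concatenate([qc_pos, unused[:n_qc - len(qc_pos)]]))
    qc_orders = inner[qc_pos]
    study_orders = np.setdiff1d(inner, qc_orders)
    rng.shuffle(study_orders)
    return study_orders, qc_orders, blank_orders


def simulate_study(truth: GroundTruth) -> tuple[StudyBundle, pd.DataFrame]:
    """Simulate one study; returns the bundle and the true latent scores.

    Per sample, latent factor scores are drawn as its cluster's mean plus
    standard normal noise (unit within-cluster variance, matching the
    standardized factor-score scale of the cluster means).  Each platform's
    intensities are ``exp(base + loading * latent + noise)`` so values are
    positive and log-normal-like.  QC samples are the study-mean profile
    times small multiplicative noise; drift multiplies study and QC samples
    alike; missing entries are MCAR; the IS channel is a constant times
    small noise, never missing and never drifting.
    """
    rng = np.random.default_rng(truth.seed)
    n_study = truth.n_study
    n_qc = truth.qc_count()

    # latent factor scores and cluster assignment
    study_ids = [f"S{i + 1:03d}" for i in range(n_study)]
    cluster_of = np.repeat(np.arange(truth.n_clusters), truth.cluster_sizes)
    within_sd, marginal_sd = truth.factor_scales()
    chol = np.linalg.cholesky(truth.within_cov())
    latent = (truth.cluster_factor_means[cluster_of]
              + rng.standard_normal((n_study, truth.n_factors)) @ chol.T)
    latent_df = pd.DataFrame(
        latent, index=study_ids,
        columns=[f"F{j + 1}" for j in range(truth.n_factors)])

    metadata = pd.DataFrame({
        "genetic_group": rng.choice(["variant", "no_variant"], size=n_study),
        "true_metabotype": cluster_of + 1,
        "age_years": np.round(rng.normal(11.0, 3.4, n_study).clip(3, 18), 1),
        "bmi_sds": np.round(rng.normal(4.2, 2.2, n_study).clip(2.0, None), 2),
        "tanner_stage": rng.choice(["I", "II", "III", "IV", "V"], size=n_study),
    }, index=pd.Index(study_ids, name="sample_id"))

    matrices = []
    for spec in truth.platform_specs:
        p = spec.n_features
        # loading matrix: disjoint blocks, zero elsewhere
        lam = np.zeros((p, truth.n_factors))
        start = 0
        for b in spec.blocks:
            lam[start:start + b.n_vars, b.factor] = b.loading
            start += b.n_vars
        n_block_vars = start
        base = rng.uniform(np.log(1e4), np.log(1e6), size=p)

        # block features: factor signal + unique noise.  The unique noise of
        # a block feature is scaled to its factor's marginal sd so the
        # standardized within-block loading hits ``block_loading_std``
        # whatever the factor's between-cluster spread.  Diffuse features:
        # weak cross-loadings on several latent factors + unique residual.
        # Everything is scaled by noise_sd so the noiseless limit is
        # degenerate.
        lt = min(max(truth.block_loading_std, 0.1), 0.999)
        noise_scale = np.full(p, truth.noise_sd)
        start2 = 0
        for b in spec.blocks:
            sig_sd = b.loading * marginal_sd[b.factor]
            # proportional to noise_sd; hits the target standardized
            # loading exactly at the default noise level
            noise_scale[start2:start2 + b.n_vars] = (
                sig_sd * np.sqrt(1.0 - lt ** 2) / lt
                * (truth.noise_sd / REFERENCE_NOISE_SD))
            start2 += b.n_vars
        noise = noise_scale * rng.standard_normal((n_study, p))
        log_study = base[None, :] + latent @ lam.T + noise
        n_free = p - n_block_vars
        if n_free > 0 and spec.crossload_k > 0 and truth.noise_sd > 0:
            # standardize the cross-loadings against each factor's true
            # marginal sd (within-cluster variance + between-cluster spread
            # of the metabotype means)
            factor_sd = marginal_sd
            own = [b.factor for b in spec.blocks]
            # metabotype structure correlates some factors; a diffuse family
            # pairs its anchor with the factor least correlated with it so
            # its two cross-loadings stay a genuine double saturation
            w_arr = np.asarray(truth.cluster_sizes, float)
            w_arr = w_arr / w_arr.sum()
            dm = truth.cluster_factor_means - w_arr @ truth.cluster_factor_means
            bcov = (dm * w_arr[:, None]).T @ dm
            denom = np.outer(marginal_sd, marginal_sd)
            bcorr = np.abs(bcov / denom)
            np.fill_diagonal(bcorr, np.inf)
            partner_of = np.argmin(bcorr, axis=1)
            fam_size = max(spec.family_size, 1)
            n_fam = int(np.ceil(n_free / fam_size))
            tau = spec.diffuse_scale * truth.noise_sd
            free_cols = np.empty((n_study, n_free))
            col = 0
            for _ in range(n_fam):
                kc = min(spec.crossload_k, truth.n_factors)
                if own:
                    anchor = int(rng.choice(own))
                else:
                    anchor = int(rng.choice(truth.n_factors))
                support = [anchor]
                while len(support) < kc:
                    nxt = int(partner_of[support[-1]])
                    if nxt in support:  # fall back to any unused factor
                        pool = [f for f in range(truth.n_factors)
                                if f not in support]
                        nxt = int(rng.choice(pool))
                    support.append(nxt)
                load = spec.crossload_loading
                w = np.zeros(truth.n_factors)
                w[support] = (rng.choice([-1.0, 1.0], size=kc)
                              * load / factor_sd[support])
                comm = kc * load ** 2
                res_frac = max(1.0 - comm, 1e-12)
                # shared fraction of the residual chosen so the
                # within-family correlation hits the family_r target
                rho = min(max((spec.family_r - comm) / res_frac, 0.0), 1.0)
                shared = (latent @ w
                          + np.sqrt(res_frac * rho)
                          * rng.standard_normal(n_study))
                members = min(fam_size, n_free - col)
                eps = rng.standard_normal((n_study, members))
                free_cols[:, col:col + members] = (
                    shared[:, None] + np.sqrt(res_frac * (1 - rho)) * eps)
                col += members
            free = slice(n_block_vars, p)
            log_study[:, free] = base[None, free] + tau * free_cols
        study_vals = np.exp(log_study)

        qc_profile = study_vals.mean(axis=0)
        qc_vals = qc_profile[None, :] * np.exp(
            truth.qc_noise_sd * rng.standard_normal((n_qc, p)))
        blank_vals = qc_profile[None, :] * 0.001 * np.exp(
            0.2 * rng.standard_normal((2, p)))

        study_orders, qc_orders, blank_orders = _injection_layout(
            n_study, n_qc, rng)
        last = n_study + n_qc + 2

        study_vals = study_vals * drift_multiplier(
            study_orders, last, spec.drift_a, spec.drift_b)[:, None]
        qc_vals = qc_vals * drift_multiplier(
            qc_orders, last, spec.drift_a, spec.drift_b)[:, None]

        # MCAR missingness on study + QC measured channels
        vals = np.vstack([study_vals, qc_vals, blank_vals])
        if truth.missing_rate > 0:
            mask = rng.random((n_study + n_qc, p)) < truth.missing_rate
            vals[:n_study + n_qc][mask] = np.nan

        # internal standard: constant response, no drift, never missing
        is_id = f"IS_{spec.platform_id}"
        is_col = 5e5 * np.exp(0.02 * rng.standard_normal((vals.shape[0], 1)))

        qc_ids = [f"QC{i + 1:02d}" for i in range(n_qc)]
        blank_ids = ["BLANK1", "BLANK2"]
        index = pd.Index(study_ids + qc_ids + blank_ids, name="sample_id")
        feature_ids = [f"{spec.platform_id}_V{j + 1:03d}" for j in range(p)]
        values = pd.DataFrame(np.hstack([vals, is_col]), index=index,
                              columns=feature_ids + [is_id])
        roles = pd.Series(["study"] * n_study + ["qc"] * n_qc + ["blank"] * 2,
                          index=index)
        orders = pd.Series(
            np.concatenate([study_orders, qc_orders, blank_orders]),
            index=index, dtype=int)
        matrices.append(FeatureMatrix(
            platform_id=spec.platform_id, values=values, sample_roles=roles,
            injection_order=orders, is_features=(is_id,)))

    bundle = StudyBundle(matrices=matrices, metadata=metadata)
    return bundle, latent_df


def true_block_membership(truth: GroundTruth) -> dict[str, int]:
    """Map feature id -> planted factor index (0-based) for block features."""
    membership: dict[str, int] = {}
    for spec in truth.platform_specs:
        start = 0
        for b in spec.blocks:
            for j in range(start, start + b.n_vars):
                membership[f"{spec.platform_id}_V{j + 1:03d}"] = b.factor
            start += b.n_vars
    return membership


# ---------------------------------------------------------------------------
# tiny hand-checkable fixture
# ---------------------------------------------------------------------------

def known_answer_fixture() -> StudyBundle:
    """A tiny two-platform bundle with hand-checkable values.

    Shipped in the repository (10 samples, <= 10 features per platform,
    3 QCs each) so unit tests for parsing, alignment and kNN imputation have
    a fixed, human-auditable input.
    """
    root = importlib.resources.files("metabotyper") / "data" / "known_answer"
    with importlib.resources.as_file(root) as base:
        m1 = read_feature_matrix(base / "alpha.csv", "alpha", is_features=("IS_alpha",))
        m2 = read_feature_matrix(base / "beta.csv", "beta", is_features=("IS_beta",))
        meta = read_metadata(base / "metadata.csv")
    return StudyBundle(matrices=[m1, m2], metadata=meta)


# ---------------------------------------------------------------------------
# bundle writer (used by the `simulate` CLI subcommand)
# ---------------------------------------------------------------------------

def write_bundle(bundle: StudyBundle, truth: GroundTruth | None,
                 outdir: str | Path) -> None:
    """Write a bundle in the standard file layout plus a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in bundle.matrices:
        write_feature_matrix(m, outdir / f"{m.platform_id}.csv")
    write_metadata(bundle.metadata, outdir / "metadata.csv")
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))


def read_bundle(paths: Sequence[str | Path], metadata_path: str | Path,
                is_features: dict[str, Sequence[str]] | None = None) -> StudyBundle:
    """Read a bundle from per-platform files named ``<platform_id>.<ext>``."""
    is_features = is_features or {}
    matrices = []
    for p in paths:
        pid = Path(p).stem
        matrices.append(read_feature_matrix(p, pid, is_features.get(pid, ())))
    return StudyBundle(matrices=matrices, metadata=read_metadata(metadata_path))
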