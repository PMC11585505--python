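"""Probe QC, BMIQ-style normalization, covariate screening, and batch correction.

The preprocessing stage mirrors the standard methylation-array workflow for
Illumina EPIC-like beta matrices: probes overlapping SNPs, probes on sex
chromosomes, and probes failing detection are removed; samples measured on
several arrays are restricted to their shared CpGs; the type II probe beta
distribution is rescaled onto the type I distribution (beta-mixture quantile
dilation); principal components are screened against technical and biological
covariates; and batch effects are removed by parametric empirical-Bayes
location/scale adjustment on logit-transformed betas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc, digamma, expit, logit

logger = logging.getLogger("pitmeth")

#: closed vocabulary for the tumour group column of a sample sheet
GROUPS = ("benign", "APT", "PC")

#: columns every sample sheet must carry
SHEET_COLUMNS = (
    "sample", "group", "first_surgery", "lineage",
    "functional", "slide", "array", "sex", "age",
)

_LOGIT_EPS = 1e-3  # beta clamp before logit transforms


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with companion detection p-values.

    Parameters
    ----------
    values
        DataFrame of beta values in [0, 1]; index = probe ids, columns =
        sample ids, both unique.
    detection_p
        Optional DataFrame of detection p-values with the same shape and
        labels as ``values``.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated probe identifiers in beta matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample identifiers in beta matrix")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection p-value matrix shape mismatch")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probes) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p.loc[probes]
        return BetaMatrix(self.values.loc[probes], det)

    def subset_samples(self, samples) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p[list(samples)]
        return BetaMatrix(self.values[list(samples)], det)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the closed vocabulary and required columns of a sample sheet."""
    for col in SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    bad = set(sheet["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown tumour group labels: {sorted(bad)}")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicated sample identifiers in sample sheet")
    return sheet


@dataclass
class FilterReport:
    """Per-rule tally of the probe QC filter.

    Rules are applied in order SNP overlap -> sex chromosome -> detection
    failure; each probe is counted once, under the first rule that removes it,
    so ``removed_snp + removed_sex + removed_detection + retained == initial``.
    """

    initial: int
    removed_snp: int
    removed_sex: int
    removed_detection: int
    retained: int

    def __post_init__(self) -> None:
        total = self.removed_snp + self.removed_sex + self.removed_detection + self.retained
        if total != self.initial:
            raise ValueError("filter report does not reconcile")

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "removed_snp": self.removed_snp,
            "removed_sex": self.removed_sex,
            "removed_detection": self.removed_detection,
            "retained": self.retained,
        }


# ---------------------------------------------------------------------------
# probe filtering and intersection
# ---------------------------------------------------------------------------

def filter_probes(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    detection_threshold: float = 0.01,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove SNP-overlapping, sex-chromosome, and detection-failing probes.

    A probe is dropped if it is SNP-flagged, or lies on a sex chromosome, or
    has detection p > ``detection_threshold`` in at least one sample.
    """
    if not 0 < detection_threshold < 1:
        raise ValueError("detection threshold must be in (0, 1)")
    missing = beta.probes.difference(manifest.index)
    if len(missing):
        raise ValueError(f"probe {missing[0]!r} missing from manifest")

    ann = manifest.loc[beta.probes]
    snp = ann["snp"].to_numpy(bool)
    sex = ann["sex_chrom"].to_numpy(bool)
    if beta.detection_p is not None:
        det_fail = (beta.detection_p.to_numpy(float) > detection_threshold).any(axis=1)
    else:
        det_fail = np.zeros(len(beta.probes), bool)

    removed_snp = snp
    removed_sex = sex & ~removed_snp
    removed_det = det_fail & ~snp & ~sex
    keep = ~(snp | sex | det_fail)

    report = FilterReport(
        initial=len(beta.probes),
        removed_snp=int(removed_snp.sum()),
        removed_sex=int(removed_sex.sum()),
        removed_detection=int(removed_det.sum()),
        retained=int(keep.sum()),
    )
    return beta.subset_probes(beta.probes[keep]), report


def shared_probes(
    matrices: list[BetaMatrix],
    manifest: pd.DataFrame | None = None,
) -> BetaMatrix:
    """Column-wise concatenation restricted to the probes shared by all matrices.

    Probe order follows ``manifest`` genomic order when given, otherwise the
    order of the first matrix.
    """
    if not matrices:
        raise ValueError("need at least one beta matrix")
    common = matrices[0].probes
    for m in matrices[1:]:
        common = common.intersection(m.probes)
    if len(common) == 0:
        raise ValueError("no shared probes across matrices")
    if manifest is not None:
        order = manifest.index[manifest.index.isin(common)]
    else:
        order = matrices[0].probes[matrices[0].probes.isin(common)]
    values = pd.concat([m.values.loc[order] for m in matrices], axis=1)
    if all(m.detection_p is not None for m in matrices):
        det = pd.concat([m.detection_p.loc[order] for m in matrices], axis=1)
    else:
        det = None
    return BetaMatrix(values, det)


# ---------------------------------------------------------------------------
# beta-mixture quantile dilation (type II -> type I rescaling)
# ---------------------------------------------------------------------------

def _fit_beta_mixture(
    x: np.ndarray,
    init_means=(0.1, 0.5, 0.9),
    init_dispersion: float = 10.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    rtol_floor: float = 1e-10,
):
    """EM fit of a three-component beta mixture on (0, 1) data.

    Component shapes are updated by weighted method of moments, which is the
    standard stable choice on bounded methylation data. Returns (weights,
    a, b, responsibilities) with components ordered by mean.
    """
    x = np.clip(np.asarray(x, float), 1e-6, 1 - 1e-6)
    k = len(init_means)
    means = np.asarray(init_means, float)
    a = means * init_dispersion
    b = (1 - means) * init_dispersion
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    resp = np.full((x.size, k), 1.0 / k)
    for _ in range(max_iter):
        logpdf = np.column_stack(
            [stats.beta.logpdf(x, a[j], b[j]) for j in range(k)]
        ) + np.log(w)
        mx = logpdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        resp = np.exp(logpdf - lse[:, None])
        ll = lse.sum()
        nk = resp.sum(axis=0)
        if (nk < 1.0).any():
            break  # empty component; keep last stable parameters
        w = nk / x.size
        m = resp.T @ x / nk
        v = np.einsum("ij,ij->j", resp, (x[:, None] - m) ** 2) / nk
        v = np.maximum(v, rtol_floor)
        s = np.maximum(m * (1 - m) / v - 1, 0.1)
        a = np.clip(m * s, 1e-3, 1e6)
        b = np.clip((1 - m) * s, 1e-3, 1e6)
        if abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            break
        prev_ll = ll
    order = np.argsort(a / (a + b))
    return w[order], a[order], b[order], resp[:, order]


def _beta_quantile_map(x, a_from, b_from, a_to, b_to):
    p = np.clip(betainc(a_from, b_from, np.clip(x, 1e-9, 1 - 1e-9)), 1e-12, 1 - 1e-12)
    return stats.beta.ppf(p, a_to, b_to)


def bmiq_normalize(beta: BetaMatrix, manifest: pd.DataFrame) -> BetaMatrix:
    """Map type II probe betas onto the type I distribution, per sample.

    For each sample a three-state (unmethylated / hemimethylated / methylated)
    beta mixture is fit separately to type I and type II probes. Type II
    probes classified to the U and M states are transferred onto the type I
    U and M component distributions by beta quantile matching; the middle
    (H) state is carried across by a linear dilation anchored at the mapped
    state boundaries. Type I probes are returned unchanged and the
    within-sample rank order of type II probes is preserved.
    """
    design = manifest.loc[beta.probes, "design_type"]
    is_t2 = (design == "II").to_numpy()
    if (~is_t2).sum() < 50 or is_t2.sum() < 50:
        raise ValueError("need at least 50 probes of each design type per sample")

    out = beta.values.copy()
    vals = beta.values.to_numpy(float)
    for si, sample in enumerate(beta.samples):
        x1 = vals[~is_t2, si]
        x2 = vals[is_t2, si]
        try:
            _, a1, b1, _ = _fit_beta_mixture(x1)
            _, a2, b2, r2 = _fit_beta_mixture(x2)
        except Exception:  # pragma: no cover - defensive
            logger.warning("BMIQ mixture fit failed for sample %s; left unchanged", sample)
            continue
        labels = r2.argmax(axis=1)
        if not ((labels == 0).any() and (labels == 2).any()):
            logger.warning("BMIQ empty mixture state for sample %s; left unchanged", sample)
            continue
        u_right = x2[labels == 0].max()
        m_left = x2[labels == 2].min()
        if u_right >= m_left:
            logger.warning("BMIQ overlapping states for sample %s; left unchanged", sample)
            continue
        # re-assign by value so the piecewise map is globally monotone
        in_u = x2 <= u_right
        in_m = x2 >= m_left
        in_h = ~(in_u | in_m)
        mapped = x2.copy()
        mapped[in_u] = _beta_quantile_map(x2[in_u], a2[0], b2[0], a1[0], b1[0])
        mapped[in_m] = _beta_quantile_map(x2[in_m], a2[2], b2[2], a1[2], b1[2])
        u_right_new = _beta_quantile_map(np.array([u_right]), a2[0], b2[0], a1[0], b1[0])[0]
        m_left_new = _beta_quantile_map(np.array([m_left]), a2[2], b2[2], a1[2], b1[2])[0]
        if m_left_new <= u_right_new:
            logger.warning("BMIQ boundary inversion for sample %s; left unchanged", sample)
            continue
        if in_h.any():
            scale = (m_left_new - u_right_new) / (m_left - u_right)
            mapped[in_h] = u_right_new + (x2[in_h] - u_right) * scale
        col = vals[:, si].copy()
        col[is_t2] = np.clip(mapped, 0.0, 1.0)
        out.iloc[:, si] = col
    return BetaMatrix(out, beta.detection_p)


# ---------------------------------------------------------------------------
# SVD covariate screen
# ---------------------------------------------------------------------------

def svd_covariate_screen(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    n_components: int,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Associate leading singular vectors with technical/biological covariates.

    Components of the row-centred beta matrix are tested against each
    covariate: categorical covariates by a Kruskal-Wallis rank test,
    continuous covariates by a Pearson correlation test. Returns a
    (component x covariate) table of p-values.
    """
    sheet = validate_sample_sheet(sheet).set_index("sample").loc[beta.samples]
    n_samples = len(beta.samples)
    if n_components > n_samples - 1:
        raise ValueError("n_components must be at most samples - 1")
    if covariates is None:
        covariates = ["group", "lineage", "functional", "slide", "array", "sex", "age"]

    x = beta.values.to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:n_components]  # component scores over samples

    rows = {}
    for ci in range(n_components):
        scores = comps[ci]
        pvals = {}
        for cov in covariates:
            col = sheet[cov]
            if col.nunique(dropna=True) < 2:
                logger.warning("covariate %r constant across samples; skipped", cov)
                continue
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                _, p = stats.pearsonr(scores, col.to_numpy(float))
            else:
                groups = [scores[(col == lv).to_numpy()] for lv in col.unique()]
                _, p = stats.kruskal(*groups)
            pvals[cov] = p
        rows[f"PC{ci + 1}"] = pvals
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction on logit(beta)
# ---------------------------------------------------------------------------

def _squeeze_batch_params(z_std, batch_idx, n_batches, tol=1e-4, max_iter=100):
    """Empirical-Bayes shrinkage of per-batch location/scale (parametric).

    Normal prior on the per-probe batch location, inverse-gamma on the batch
    scale; hyperparameters by method of moments; the posterior point
    estimates are solved by the standard fixed-point iteration.
    """
    gamma_star, delta_star = [], []
    for b in range(n_batches):
        zb = z_std[:, batch_idx == b]
        nb = zb.shape[1]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, v = d_hat.mean(), d_hat.var(ddof=1)
        if v <= 0:
            a_prior, b_prior = 2.0, m
        else:
            a_prior = (2 * v + m ** 2) / v
            b_prior = (m * v + m ** 3) / v
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_prev, d_prev = g_new, d_new
            g_new = (t2 * nb * g_hat + d_prev * g_bar) / (t2 * nb + d_prev)
            sum2 = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (nb / 2.0 + a_prior - 1)
            change = max(
                np.abs(g_new - g_prev).max() / (np.abs(g_prev).max() + 1e-12),
                np.abs(d_new - d_prev).max() / (np.abs(d_prev).max() + 1e-12),
            )
            if change < tol:
                break
        gamma_star.append(g_new)
        delta_star.append(d_new)
    return np.array(gamma_star), np.array(delta_star)


def combat_correct(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    batch_field: str = "slide",
    protect: str | None = "group",
) -> BetaMatrix:
    """Parametric empirical-Bayes batch adjustment on logit-transformed betas.

    The protected biological term (``protect``, e.g. tumour group) is kept in
    the standardization model so real group differences are not absorbed into
    the batch estimates. Output is mapped back to [0, 1].
    """
    sheet = validate_sample_sheet(sheet).set_index("sample").loc[beta.samples]
    if batch_field not in sheet.columns:
        raise ValueError(f"batch field {batch_field!r} missing from sample sheet")
    batch = sheet[batch_field].astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        logger.warning("single batch; batch correction is the identity")
        return BetaMatrix(beta.values.copy(), beta.detection_p)
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 samples")

    batch_idx = np.array([levels.index(b) for b in batch])
    n_batches = len(levels)
    n = len(beta.samples)
    B = np.zeros((n, n_batches))
    B[np.arange(n), batch_idx] = 1.0

    if protect is not None:
        prot = pd.get_dummies(sheet[protect].astype(str), drop_first=True).to_numpy(float)
        if prot.size:
            full = np.column_stack([B, prot])
            if np.linalg.matrix_rank(full) < full.shape[1]:
                raise ValueError(
                    f"batch field {batch_field!r} is confounded with protected field {protect!r}"
                )
        z_design = prot
    else:
        z_design = np.empty((n, 0))

    x = np.clip(beta.values.to_numpy(float), _LOGIT_EPS, 1 - _LOGIT_EPS)
    x = logit(x)

    design = np.column_stack([B, z_design])
    b_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    batch_sizes = np.bincount(batch_idx, minlength=n_batches).astype(float)
    grand_mean = (batch_sizes / n) @ b_hat[:n_batches]
    cov_effect = (z_design @ b_hat[n_batches:]).T if z_design.size else 0.0
    stand_mean = grand_mean[:, None] + cov_effect
    resid = x - (design @ b_hat).T
    var_pooled = np.maximum((resid ** 2).mean(axis=1), 1e-8)

    z_std = (x - stand_mean) / np.sqrt(var_pooled)[:, None]
    gamma_star, delta_star = _squeeze_batch_params(z_std, batch_idx, n_batches)

    adj = np.empty_like(x)
    for b in range(n_batches):
        cols = batch_idx == b
        adj[:, cols] = (z_std[:, cols] - gamma_star[b][:, None]) / np.sqrt(delta_star[b])[:, None]
    adj = adj * np.sqrt(var_pooled)[:, None] + stand_mean

    corrected = pd.DataFrame(expit(adj), index=beta.probes, columns=beta.samples)
    return BetaMatrix(corrected, beta.detection_p)
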