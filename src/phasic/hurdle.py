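"""Two-part (hurdle) regression for single-cell / pseudobulk expression.

A gene's expression across units is modeled with two components:

* a **discrete** logistic regression of the detection indicator
  (``expression > 0``) on the design, and
* a **continuous** Gaussian regression of expression on the design,
  restricted to the units where the gene is detected.

A model term is tested by a likelihood-ratio chi-square summed over the two
components, with degrees of freedom equal to the number of deleted columns
in each component that is alive for that gene.  Degenerate components are
dropped and contribute nothing to the test: the continuous part when there
are not enough detected units to estimate the coefficients and a residual
variance, the discrete part when either detection class has no more units
than coefficients (which covers all-/none-detected genes and the
quasi-separated near-saturation regime, where the logistic LRT has no
usable chi-square reference).

All fitting is exact maximum likelihood (the continuous variance is the ML
estimate RSS/n).  A tiny ridge penalty (1e-6) on the discrete coefficients
keeps the likelihood finite under perfect separation.

The module exposes both a scalar API (:func:`fit_hurdle`, :func:`lrt_term`)
and batched drivers that fit thousands of genes sharing one design matrix
simultaneously; the pipelines use the batched path.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, expit

from .containers import ValidationError

RIDGE = 1e-6
VALID_TERMS = ("cell_cycle_phase", "lineage", "cell_cycle_phase:lineage",
               "fraction_of_detected_genes")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class HurdleDesign:
    """Treatment-coded design matrix for the hurdle regressions."""

    matrix: np.ndarray                  # units x coefficients
    columns: list[str]
    terms: list[str]
    term_cols: dict[str, list[int]]     # term -> column indices
    reference_lineage: str | None = None
    lineages: list[str] = field(default_factory=list)
    interaction_cols: dict[str, int] = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]


def build_design(annotations: pd.DataFrame, terms,
                 reference_lineage: str | None = None) -> HurdleDesign:
    """Build a treatment-coded design from a unit annotation table.

    Allowed terms: ``cell_cycle_phase``, ``lineage``,
    ``cell_cycle_phase:lineage`` and ``fraction_of_detected_genes``.  The
    intercept is always present.  The reference lineage (default: first in
    sorted order) contributes no dummy column.
    """
    terms = list(terms)
    for t in terms:
        if t not in VALID_TERMS:
            raise ValidationError(f"unknown design term {t!r}")
    if "cell_cycle_phase:lineage" in terms:
        if "cell_cycle_phase" not in terms or "lineage" not in terms:
            raise ValidationError("interaction requires both main effects")
    n = len(annotations)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {}
    lineages: list[str] = []
    interaction_cols: dict[str, int] = {}

    phase_dummy = None
    if "cell_cycle_phase" in terms:
        phase_dummy = (annotations["phase"].to_numpy() == "G2M").astype(float)
        if phase_dummy.min() == phase_dummy.max():
            raise ValidationError("need both phase levels in the design")
        term_cols["cell_cycle_phase"] = [len(cols)]
        cols.append(phase_dummy)
        names.append("phaseG2M")

    lineage_dummies: dict[str, np.ndarray] = {}
    if "lineage" in terms:
        lin = annotations["lineage"].astype(str).to_numpy()
        lineages = sorted(set(lin))
        if len(lineages) < 2:
            raise ValidationError("lineage term requested with a single lineage")
        if reference_lineage is None:
            reference_lineage = lineages[0]
        if reference_lineage not in lineages:
            raise ValidationError(f"reference lineage {reference_lineage!r} absent")
        term_cols["lineage"] = []
        for name in lineages:
            if name == reference_lineage:
                continue
            d = (lin == name).astype(float)
            lineage_dummies[name] = d
            term_cols["lineage"].append(len(cols))
            cols.append(d)
            names.append(f"lineage[{name}]")

    if "cell_cycle_phase:lineage" in terms:
        term_cols["cell_cycle_phase:lineage"] = []
        for name, d in lineage_dummies.items():
            term_cols["cell_cycle_phase:lineage"].append(len(cols))
            interaction_cols[name] = len(cols)
            cols.append(phase_dummy * d)
            names.append(f"phaseG2M:lineage[{name}]")

    if "fraction_of_detected_genes" in terms:
        frac = annotations["detection_fraction"].to_numpy(dtype=float)
        term_cols["fraction_of_detected_genes"] = [len(cols)]
        cols.append(frac)
        names.append("detection")

    X = np.column_stack(cols)
    return HurdleDesign(X, names, terms, term_cols, reference_lineage,
                        lineages, interaction_cols)


# ---------------------------------------------------------------------------
# batched component fits
# ---------------------------------------------------------------------------

def _logistic_penalized_ll(B: np.ndarray, Z: np.ndarray, X: np.ndarray,
                           ridge: float) -> np.ndarray:
    eta = np.clip(B @ X.T, -30, 30)
    ll = Z * eta - np.logaddexp(0.0, eta)
    return ll.sum(axis=1) - 0.5 * ridge * (B ** 2).sum(axis=1)


def fit_logistic_batch(Z: np.ndarray, X: np.ndarray, ridge: float = RIDGE,
                       max_iter: int = 100, tol: float = 1e-10
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized logistic ML for G genes sharing one design.

    Z is G x n binary, X is n x p.  Returns ``(beta, loglik)`` where
    *loglik* is the **unpenalized** log-likelihood at the penalized optimum
    (the penalty only stabilizes separation and is numerically negligible
    otherwise).  Damped Newton with vectorized step-halving.
    """
    Z = np.asarray(Z, dtype=float)
    G, n = Z.shape
    p = X.shape[1]
    B = np.zeros((G, p))
    eye = np.eye(p)[None, :, :]
    ll = _logistic_penalized_ll(B, Z, X, ridge)
    for _ in range(max_iter):
        eta = np.clip(B @ X.T, -30, 30)
        mu = expit(eta)
        grad = (Z - mu) @ X - ridge * B
        if np.abs(grad).max() < tol:
            break
        W = mu * (1.0 - mu)
        H = np.einsum("gn,np,nq->gpq", W, X, X) + ridge * eye
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        alpha = np.ones(G)
        for _ in range(30):
            Bnew = B + alpha[:, None] * step
            llnew = _logistic_penalized_ll(Bnew, Z, X, ridge)
            bad = llnew < ll - 1e-13
            if not bad.any():
                break
            alpha[bad] *= 0.5
        B, ll = Bnew, llnew
    eta = np.clip(B @ X.T, -30, 30)
    loglik = (Z * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    return B, loglik


def fit_gaussian_batch(Y: np.ndarray, X: np.ndarray, W: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indicator-weighted least squares for G genes sharing one design.

    W is a G x n 0/1 detection mask; the fit is OLS restricted to detected
    units.  Returns ``(beta, rss, loglik)`` with the Gaussian ML
    log-likelihood (sigma^2 = RSS / n_detected).  Genes whose restricted
    normal equations are singular fall back to a minimum-norm solution.
    """
    G, n = Y.shape
    p = X.shape[1]
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X)
    XtWy = np.einsum("np,gn->gp", X, W * Y)
    try:
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        resid_ok = np.isfinite(beta).all(axis=1)
    except np.linalg.LinAlgError:
        beta = np.full((G, p), np.nan)
        resid_ok = np.zeros(G, dtype=bool)
    # verify the solve; rank-deficient genes get a pinv fallback
    check = np.einsum("gpq,gq->gp", XtWX, np.nan_to_num(beta)) - XtWy
    bad = ~resid_ok | (np.abs(check).max(axis=1) >
                       1e-6 * (1.0 + np.abs(XtWy).max(axis=1)))
    for g in np.flatnonzero(bad):
        beta[g] = np.linalg.pinv(XtWX[g]) @ XtWy[g]
    ndet = W.sum(axis=1)
    rss = np.einsum("gn,gn->g", W, Y ** 2) - np.einsum("gp,gp->g", beta, XtWy)
    rss = np.maximum(rss, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = -0.5 * ndet * (np.log(2.0 * np.pi * rss / np.maximum(ndet, 1)) + 1.0)
    return beta, rss, loglik


# ---------------------------------------------------------------------------
# batched LRT
# ---------------------------------------------------------------------------

def hurdle_lrt_batch(Y: np.ndarray, design: HurdleDesign, drop_cols,
                     effect_col: int | None = None) -> pd.DataFrame:
    """Likelihood-ratio test of the coefficients *drop_cols* for every gene.

    Y is G x n expression on the modeled (non-negative) scale.  Returns a
    frame with ``chisq``, ``df``, ``p_value``, ``log2fc`` (the full-model
    continuous coefficient at *effect_col*; NA when the continuous part is
    dropped) and ``testable``.
    """
    Y = np.asarray(Y, dtype=float)
    X = design.matrix
    drop_cols = np.asarray(sorted(drop_cols), dtype=int)
    keep = np.setdiff1d(np.arange(X.shape[1]), drop_cols)
    Xr = X[:, keep]
    G, n = Y.shape
    p = X.shape[1]
    q = drop_cols.size
    Z = (Y > 0)
    ndet = Z.sum(axis=1)
    # the discrete component needs more units than coefficients in each
    # detection class, otherwise the logistic ML quasi-separates and its
    # LRT has no usable chi-square reference (see methods note)
    disc_live = np.minimum(ndet, n - ndet) > p
    cont_live = ndet >= p + 2

    chisq = np.zeros(G)          # raw summed 2*(ll_full - ll_reduced)
    chisq_cal = np.zeros(G)      # Bartlett-calibrated version used for p
    df = np.zeros(G, dtype=int)
    log2fc = np.full(G, np.nan)

    if disc_live.any():
        Zl = Z[disc_live].astype(float)
        _, ll_full = fit_logistic_batch(Zl, X)
        _, ll_red = fit_logistic_batch(Zl, Xr)
        stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        chisq[disc_live] += stat
        chisq_cal[disc_live] += stat
        df[disc_live] += q

    if cont_live.any():
        Yl = Y[cont_live]
        Wl = Z[cont_live].astype(float)
        beta_f, rss_f, ll_full = fit_gaussian_batch(Yl, X, Wl)
        _, rss_r, ll_red = fit_gaussian_batch(Yl, Xr, Wl)
        stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        chisq[cont_live] += stat
        # Exact Bartlett factor of the Gaussian LRT: under the null,
        # E[n log(RSS_r/RSS_f)] = n (psi((n-p+q)/2) - psi((n-p)/2)),
        # from the log-chi-square moments; scaling by this mean over q
        # restores the chi-square(q) reference at small n.
        nd = ndet[cont_live].astype(float)
        bartlett = nd * (digamma((nd - p + q) / 2.0)
                         - digamma((nd - p) / 2.0)) / q
        chisq_cal[cont_live] += stat / bartlett
        df[cont_live] += q
        if effect_col is not None:
            log2fc[cont_live] = beta_f[:, effect_col]

    testable = df > 0
    p_value = np.full(G, np.nan)
    p_value[testable] = sps.chi2.sf(chisq_cal[testable], df[testable])
    return pd.DataFrame({
        "chisq": chisq,
        "df": df,
        "p_value": p_value,
        "log2fc": log2fc,
        "testable": testable,
    })


def lrt_term_batch(Y: np.ndarray, design: HurdleDesign, term: str) -> pd.DataFrame:
    """LRT of one named model term (all of its columns deleted at once)."""
    if term not in design.term_cols:
        raise ValidationError(f"term {term!r} not in design")
    cols = design.term_cols[term]
    effect_col = None
    if term == "cell_cycle_phase":
        effect_col = cols[0]
    return hurdle_lrt_batch(Y, design, cols, effect_col=effect_col)


def interaction_contrasts_batch(Y: np.ndarray, design: HurdleDesign
                                ) -> dict[str, pd.DataFrame]:
    """Per-lineage phase-by-lineage contrasts against the reference lineage.

    Each non-reference lineage's single interaction column is deleted in
    turn, asking whether that lineage's phasing differs from the reference.
    The reported effect is the interaction coefficient itself (the extra
    G2M-vs-G1 log2 difference in that lineage).
    """
    if not design.interaction_cols:
        raise ValidationError("design has no interaction columns")
    out = {}
    for lineage, col in design.interaction_cols.items():
        out[lineage] = hurdle_lrt_batch(Y, design, [col], effect_col=col)
    return out


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

@dataclass
class HurdleFit:
    """Fitted two-component hurdle model for a single gene."""

    beta_discrete: np.ndarray | None
    beta_continuous: np.ndarray | None
    sigma2: float | None
    loglik_discrete: float
    loglik_continuous: float
    df_discrete: int
    df_continuous: int
    degenerate_flags: tuple[str, ...]

    @property
    def loglik(self) -> float:
        return self.loglik_discrete + self.loglik_continuous

    @property
    def testable(self) -> bool:
        return len(self.degenerate_flags) < 2


@dataclass
class TermTest:
    """Chi-square LRT of one model term for a single gene."""

    gene_id: str
    term: str
    chisq: float
    df: int
    p_value: float
    log2fc: float


def fit_hurdle(y, design: HurdleDesign) -> HurdleFit:
    """Exact ML fit of the two-component hurdle model for one gene."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValidationError("expression values must be non-negative")
    X = design.matrix
    n, p = X.shape
    z = y > 0
    ndet = int(z.sum())
    flags: list[str] = []
    beta_d = None
    ll_d = 0.0
    df_d = 0
    if min(ndet, n - ndet) > p:
        B, ll = fit_logistic_batch(z[None, :].astype(float), X)
        beta_d, ll_d, df_d = B[0], float(ll[0]), p
    else:
        flags.append("discrete_dropped")
    beta_c = None
    sigma2 = None
    ll_c = 0.0
    df_c = 0
    if ndet >= p + 2:
        B, rss, ll = fit_gaussian_batch(y[None, :], X, z[None, :].astype(float))
        beta_c, sigma2 = B[0], float(rss[0] / ndet)
        ll_c, df_c = float(ll[0]), p
    else:
        flags.append("continuous_dropped")
    return HurdleFit(beta_d, beta_c, sigma2, ll_d, ll_c, df_d, df_c, tuple(flags))


def lrt_term(y, design: HurdleDesign, term: str, gene_id: str = "gene") -> TermTest:
    """Scalar LRT of one term; NA fields for untestable genes."""
    y = np.asarray(y, dtype=float)
    res = lrt_term_batch(y[None, :], design, term)
    row = res.iloc[0]
    if not row["testable"]:
        return TermTest(gene_id, term, np.nan, 0, np.nan, np.nan)
    return TermTest(gene_id, term, float(row["chisq"]), int(row["df"]),
                    float(row["p_value"]), float(row["log2fc"]))
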