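"""Five-model genetic association engine for quantitative traits.

Each variant-expression pair is tested under five classical genetic
models and scored by the smallest p-value among them (the min-P
statistic):

* ``ADD``       — linear regression of expression on allele dosage g
                  (0/1/2); two-sided t-test on the slope, df = n-2.
* ``DOM``       — dosage recoded 1 if g >= 1 (carrier) else 0.
* ``REC``       — dosage recoded 1 if g == 2 else 0.
* ``GENO_2DF``  — joint fit y ~ g + het with het = [g == 1]; F-test of
                  both coefficients, df = (2, n-3).  Equivalent to a
                  genotype-as-factor 2-df test.
* ``DOMDEV``    — t-test on the het coefficient in the same joint fit
                  (deviation from additivity), df = n-3.

Missing genotype or expression values are dropped pairwise.  A model is
inestimable (p = NA) when its design is constant or rank-deficient —
e.g. GENO_2DF and DOMDEV when no heterozygotes are present.  Ties in
min-P are broken by the fixed model order ADD < GENO_2DF < DOMDEV <
DOM < REC so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .model import MISSING, Variant

MODEL_ORDER: tuple[str, ...] = ("ADD", "GENO_2DF", "DOMDEV", "DOM", "REC")

# relative determinant threshold below which the 2-predictor design is
# treated as rank-deficient
_RANK_TOL = 1e-10


@dataclass
class ModelFit:
    model: str
    beta: Optional[float]  # None for GENO_2DF (no single effect)
    stat: Optional[float]
    df: Union[int, tuple[int, int], None]
    p: float  # NaN when inestimable
    n_used: int

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.p)


@dataclass
class AssociationResult:
    variant: Variant
    probe: str
    population: str
    fits: dict[str, ModelFit]
    min_p: float
    best_model: Optional[str]

    @property
    def estimable(self) -> bool:
        return self.best_model is not None


def encode(genotype: int, model: str) -> Union[int, tuple[int, int]]:
    """Encode a non-missing genotype code under a genetic model."""
    g = int(genotype)
    if g not in (0, 1, 2):
        raise ValueError(f"genotype code must be 0/1/2, got {g}")
    if model == "ADD":
        return g
    if model == "DOM":
        return 1 if g >= 1 else 0
    if model == "REC":
        return 1 if g == 2 else 0
    if model in ("GENO_2DF", "DOMDEV"):
        return (g, 1 if g == 1 else 0)
    raise ValueError(f"unknown model {model!r}")


def _simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, int, float]:
    """Slope, t, df, p for y = b0 + b1*x (two-sided t on b1)."""
    n = y.size
    if n < 3:
        return np.nan, np.nan, max(n - 2, 0), np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return np.nan, np.nan, n - 2, np.nan
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    if syy <= 0:  # constant response: no estimable effect
        return np.nan, np.nan, n - 2, np.nan
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    df = n - 2
    if rss == 0.0:
        return beta, np.inf if beta != 0 else 0.0, df, 0.0 if beta != 0 else 1.0
    se = np.sqrt(rss / df / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, t, df, p


def _joint_fit(y: np.ndarray, g: np.ndarray, het: np.ndarray):
    """Fit y ~ 1 + g + het; return (b1, b2, F, p_F, t2, p_t2, df_resid).

    Returns NaNs when the design is rank-deficient (no hets, or g and
    het collinear as when only two genotype classes {0,1} occur).
    """
    n = y.size
    nan = (np.nan,) * 6
    if n < 4:
        return (*nan, max(n - 3, 0))
    gc = g - g.mean()
    hc = het - het.mean()
    yc = y - y.mean()
    sgg = float(gc @ gc)
    shh = float(hc @ hc)
    sgh = float(gc @ hc)
    det = sgg * shh - sgh * sgh
    if sgg <= 0 or shh <= 0 or det <= _RANK_TOL * sgg * shh:
        return (*nan, n - 3)
    sgy = float(gc @ yc)
    shy = float(hc @ yc)
    syy = float(yc @ yc)
    b1 = (sgy * shh - shy * sgh) / det
    b2 = (shy * sgg - sgy * sgh) / det
    rss = max(syy - b1 * sgy - b2 * shy, 0.0)
    df = n - 3
    if syy <= 0:
        return (*nan, df)
    if rss == 0.0:
        f = np.inf
        p_f = 0.0
        t2 = np.inf if b2 != 0 else 0.0
        p_t2 = 0.0 if b2 != 0 else 1.0
        return b1, b2, f, p_f, t2, p_t2, df
    sigma2 = rss / df
    f = ((syy - rss) / 2.0) / sigma2
    p_f = stats.f.sf(f, 2, df)
    var_b2 = sigma2 * sgg / det
    t2 = b2 / np.sqrt(var_b2)
    p_t2 = 2.0 * stats.t.sf(abs(t2), df)
    return b1, b2, f, p_f, t2, p_t2, df


def fit_model(y: np.ndarray, g: np.ndarray, model: str) -> ModelFit:
    """Fit one genetic model after pairwise deletion of missing data."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    mask = (g != MISSING) & np.isfinite(y)
    yv = y[mask]
    gv = g[mask].astype(float)
    n = yv.size

    if model in ("ADD", "DOM", "REC"):
        if model == "ADD":
            x = gv
        elif model == "DOM":
            x = (gv >= 1).astype(float)
        else:
            x = (gv == 2).astype(float)
        beta, t, df, p = _simple_ols(yv, x)
        return ModelFit(model=model, beta=beta if np.isfinite(p) else None,
                        stat=t, df=df, p=p, n_used=n)

    if model in ("GENO_2DF", "DOMDEV"):
        het = (gv == 1).astype(float)
        b1, b2, f, p_f, t2, p_t2, df = _joint_fit(yv, gv, het)
        if model == "GENO_2DF":
            return ModelFit(model=model, beta=None, stat=f, df=(2, df),
                            p=p_f, n_used=n)
        return ModelFit(model=model, beta=b2 if np.isfinite(p_t2) else None,
                        stat=t2, df=df, p=p_t2, n_used=n)

    raise ValueError(f"unknown model {model!r}")


def fit_five(y: np.ndarray, g: np.ndarray) -> dict[str, ModelFit]:
    return {m: fit_model(y, g, m) for m in MODEL_ORDER}


def min_p_result(
    variant: Variant, probe: str, population: str,
    y: np.ndarray, g: np.ndarray,
) -> AssociationResult:
    """All five models; designate the smallest non-NA p as the score."""
    fits = fit_five(y, g)
    min_p = np.inf
    best = None
    for m in MODEL_ORDER:  # fixed order breaks ties deterministically
        p = fits[m].p
        if np.isfinite(p) and p < min_p:
            min_p = p
            best = m
    return AssociationResult(
        variant=variant, probe=probe, population=population,
        fits=fits, min_p=min_p if best is not None else np.nan,
        best_model=best,
    )


def batch_min_p(
    y: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Vectorized min-P over the five models for many variants at once.

    Parameters
    ----------
    y : (n_samples,) expression vector.
    G : (n_variants, n_samples) genotype codes with MISSING = -1.

    Returns
    -------
    (min_p, best_idx, p_by_model) where ``best_idx`` indexes
    ``MODEL_ORDER`` (-1 when all five models are inestimable) and
    ``p_by_model`` maps model name -> p-value array (NaN = NA).

    Agrees with :func:`fit_model` per variant; used by the cis scan and
    the permutation null for speed.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G)
    m = G.shape[0]
    valid = (G != MISSING) & np.isfinite(y)[None, :]
    n = valid.sum(axis=1).astype(float)
    Gf = np.where(valid, G, 0).astype(float)
    yv = np.where(valid, y[None, :], 0.0)

    sy = yv.sum(axis=1)
    syy = (yv * yv).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        syy_c = syy - sy * sy / n

    def simple_p(x: np.ndarray) -> np.ndarray:
        sx = x.sum(axis=1)
        sxx = (x * x).sum(axis=1)
        sxy = (x * yv).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx_c = sxx - sx * sx / n
            sxy_c = sxy - sx * sy / n
            ok = (n >= 3) & (sxx_c > 0) & (syy_c > 0)
            beta = np.where(ok, sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), np.nan)
            rss = np.maximum(syy_c - beta * sxy_c, 0.0)
            df = n - 2
            se2 = rss / np.maximum(df, 1) / np.where(sxx_c > 0, sxx_c, 1.0)
            t = np.where(se2 > 0, beta / np.sqrt(np.where(se2 > 0, se2, 1.0)), np.inf)
            p = np.where(
                ok,
                np.where(rss > 0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), 0.0),
                np.nan,
            )
        # perfect fit with zero slope: x explains nothing, y constant
        p = np.where(ok & (rss == 0) & (beta == 0), 1.0, p)
        return p

    x_add = Gf * valid
    x_dom = (Gf >= 1) & valid
    x_rec = (Gf == 2) & valid
    p_add = simple_p(x_add)
    p_dom = simple_p(x_dom.astype(float))
    p_rec = simple_p(x_rec.astype(float))

    # joint fit y ~ g + het
    h = ((Gf == 1) & valid).astype(float)
    g_ = x_add
    sg = g_.sum(axis=1)
    sh = h.sum(axis=1)
    sgg = (g_ * g_).sum(axis=1)
    shh = (h * h).sum(axis=1)
    sgh = (g_ * h).sum(axis=1)
    sgy = (g_ * yv).sum(axis=1)
    shy = (h * yv).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sgg_c = sgg - sg * sg / n
        shh_c = shh - sh * sh / n
        sgh_c = sgh - sg * sh / n
        sgy_c = sgy - sg * sy / n
        shy_c = shy - sh * sy / n
        det = sgg_c * shh_c - sgh_c * sgh_c
        ok2 = (n >= 4) & (sgg_c > 0) & (shh_c > 0) & (syy_c > 0)
        ok2 &= det > _RANK_TOL * np.maximum(sgg_c * shh_c, 1e-300)
        safe_det = np.where(ok2, det, 1.0)
        b1 = (sgy_c * shh_c - shy_c * sgh_c) / safe_det
        b2 = (shy_c * sgg_c - sgy_c * sgh_c) / safe_det
        rss = np.maximum(syy_c - b1 * sgy_c - b2 * shy_c, 0.0)
        df2 = np.maximum(n - 3, 1)
        sigma2 = rss / df2
        f = np.where(sigma2 > 0, ((syy_c - rss) / 2.0) / np.where(sigma2 > 0, sigma2, 1.0), np.inf)
        p_geno = np.where(ok2, np.where(rss > 0, stats.f.sf(f, 2, df2), 0.0), np.nan)
        var_b2 = sigma2 * sgg_c / safe_det
        t2 = np.where(var_b2 > 0, b2 / np.sqrt(np.where(var_b2 > 0, var_b2, 1.0)), np.inf)
        p_dd = np.where(
            ok2,
            np.where(rss > 0, 2.0 * stats.t.sf(np.abs(t2), df2),
                     np.where(b2 == 0, 1.0, 0.0)),
            np.nan,
        )

    p_by_model = {
        "ADD": p_add, "GENO_2DF": p_geno, "DOMDEV": p_dd,
        "DOM": p_dom, "REC": p_rec,
    }
    P = np.vstack([p_by_model[mod] for mod in MODEL_ORDER])  # 5 x m
    P_filled = np.where(np.isfinite(P), P, np.inf)
    best_idx = np.argmin(P_filled, axis=0)  # argmin keeps first = model order
    min_p = P_filled[best_idx, np.arange(m)]
    all_na = ~np.isfinite(P).any(axis=0)
    best_idx = np.where(all_na, -1, best_idx)
    min_p = np.where(all_na, np.nan, min_p)
    return min_p, best_idx, p_by_model
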