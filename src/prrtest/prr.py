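"""The permutation-of-regressor-residuals (PRR) test.

Standard likelihood-ratio tests of a covariate of interest are only as good
as the count model: on overdispersed, zero-inflated microbiome data a
misspecified family can reject most truly null taxa.  The PRR test keeps the
regression framework but builds the null distribution of the likelihood-ratio
pivotal by permutation, in three stages:

1. *Residualize.*  Replace the interest block ``X*`` (and ``Z*`` for the
   zero component) by its least-squares residual against the nuisance block:
   ``X~ = X* - X+ Sigma^``, with ``Sigma^ = argmin ||X* - X+ Sigma||^2``.
   The residuals span the same column space jointly with the nuisance
   columns, so the maximized likelihood is unchanged, but they are
   uncorrelated with the nuisance covariates and can be permuted freely.
2. *Permute.*  For each iteration ``b`` draw one random permutation of the
   sample indices and apply it to the rows of both ``X~`` and ``Z~``; refit
   and compute the chi-squared p-value of the likelihood-ratio pivotal of the
   permuted residual block against the nuisance-only fit.
3. *Compare.*  The permutation p-value is the fraction of iterations whose
   pivotal p-value falls strictly below the observed one:
   ``p = (1/B) * #{b : p_b < p_hat}``.

A multi-level categorical covariate of interest enters as m-1 treatment-coded
columns that are residualized and permuted together, and for zero-inflated
families the count and zero components are tested simultaneously (the degrees
of freedom add across components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import FamilySpec, FitResult, fit_ml, get_family

__all__ = [
    "DesignSpec",
    "ResidualizedDesign",
    "PRRResult",
    "encode_interest",
    "residualize",
    "lrt_pvalue",
    "permutation_indices",
    "prr_pvalue",
    "run_prr_test",
    "run_prr_table",
]


class DesignError(ValueError):
    """Degenerate or rank-deficient design matrix."""


@dataclass
class DesignSpec:
    """Count- and zero-component model matrices split into interest and
    nuisance blocks.

    ``X = (X_interest, X_nuisance)`` is the count-component matrix,
    ``Z = (Z_interest, Z_nuisance)`` the zero-component one; either Z block
    may be empty (non-zero-inflated families ignore Z entirely; the interest
    covariate may also be tested in the count component only).
    The nuisance blocks carry the intercept.
    """

    X_interest: np.ndarray
    X_nuisance: np.ndarray
    Z_interest: Optional[np.ndarray] = None
    Z_nuisance: Optional[np.ndarray] = None
    interest_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.X_interest = np.atleast_2d(np.asarray(self.X_interest, dtype=float))
        if self.X_interest.shape[0] == 1 and self.X_interest.shape[1] > 1:
            self.X_interest = self.X_interest.T
        self.X_nuisance = np.atleast_2d(np.asarray(self.X_nuisance, dtype=float))
        n = self.X_interest.shape[0]
        if self.X_nuisance.shape[0] != n:
            raise DesignError("X blocks disagree on the number of samples")
        for name in ("Z_interest", "Z_nuisance"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape[1] == 0:
                    v = None
                elif v.shape[0] != n:
                    raise DesignError(f"{name} disagrees on the number of samples")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.X_interest.shape[0]

    @property
    def df_interest(self) -> int:
        """Interest columns across both components: the LRT degrees of freedom."""
        p = self.X_interest.shape[1]
        s = 0 if self.Z_interest is None else self.Z_interest.shape[1]
        return p + s


@dataclass
class ResidualizedDesign:
    """Interest blocks residualized against their nuisance blocks."""

    X_resid: np.ndarray
    Sigma_hat: np.ndarray
    Z_resid: Optional[np.ndarray] = None
    Sigma_hat_Z: Optional[np.ndarray] = None


@dataclass
class PRRResult:
    """Outcome of one taxon x family PRR test."""

    p_hat: Optional[float]
    p_perm: Optional[float]
    perm_pvalues: np.ndarray
    df: int
    B: int
    n_failed: int = 0
    seed: Optional[int] = None
    converged: bool = True
    skip_reason: Optional[str] = None
    fit_full: Optional[FitResult] = None
    fit_reduced: Optional[FitResult] = None


def encode_interest(column, reference=None, name: str = "x"):
    """Encode a covariate of interest as its interest-block columns.

    A numeric column passes through as a single column.  A categorical
    (string / pandas Categorical) column with m levels becomes m-1
    treatment-coded indicator columns against ``reference`` (default: first
    level in sorted order).

    Returns ``(matrix, column_names)``.
    """
    ser = pd.Series(column)
    if pd.api.types.is_numeric_dtype(ser) and not isinstance(
        ser.dtype, pd.CategoricalDtype
    ):
        return ser.to_numpy(dtype=float)[:, None], [name]
    levels = sorted(ser.astype(str).unique())
    if len(levels) < 2:
        raise DesignError(
            f"covariate {name!r} has a single observed level ({levels[0]!r})"
        )
    if reference is None:
        reference = levels[0]
    elif str(reference) not in levels:
        raise DesignError(f"reference level {reference!r} not observed in {name!r}")
    keep = [lv for lv in levels if lv != str(reference)]
    mat = np.column_stack(
        [(ser.astype(str) == lv).to_numpy(dtype=float) for lv in keep]
    )
    return mat, [f"{name}[{lv}]" for lv in keep]


def residualize(X_interest, X_nuisance) -> ResidualizedDesign:
    """Least-squares residual of the interest block on the nuisance block.

    Solves ``argmin_Sigma ||X* - X+ Sigma||^2`` column-wise and returns
    ``X~ = X* - X+ Sigma^``; the residual columns are orthogonal to every
    nuisance column.
    """
    X_interest = np.atleast_2d(np.asarray(X_interest, dtype=float))
    if X_interest.shape[0] == 1 and X_interest.shape[1] > 1:
        X_interest = X_interest.T
    X_nuisance = np.atleast_2d(np.asarray(X_nuisance, dtype=float))
    rank = np.linalg.matrix_rank(X_nuisance)
    if rank < X_nuisance.shape[1]:
        bad = _collinear_columns(X_nuisance)
        raise DesignError(
            f"nuisance block is rank deficient (rank {rank} < "
            f"{X_nuisance.shape[1]}); collinear columns: {bad}"
        )
    sigma, *_ = np.linalg.lstsq(X_nuisance, X_interest, rcond=None)
    resid = X_interest - X_nuisance @ sigma
    return ResidualizedDesign(X_resid=resid, Sigma_hat=sigma)


def _collinear_columns(A) -> list[int]:
    from scipy.linalg import qr

    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    return sorted(int(piv[i]) for i in range(len(diag)) if diag[i] <= tol)


def lrt_pvalue(loglik_full: float, loglik_reduced: float, df: int) -> float:
    """Upper-tail chi-squared p-value of the likelihood-ratio pivotal.

    Small negative deviances (numerical noise from the nested optimizations)
    are clamped to zero.
    """
    if df <= 0:
        raise ValueError("degrees of freedom must be a positive integer")
    dev = 2.0 * (loglik_full - loglik_reduced)
    if dev < 0.0:
        dev = 0.0
    return float(stats.chi2.sf(dev, df))


def permutation_indices(n: int, B: int, seed) -> np.ndarray:
    """B independent uniform permutations of ``range(n)`` as a (B, n) array.

    The same row b must be applied to both the count- and zero-component
    residuals within an iteration.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if n < 2:
        raise ValueError("need at least 2 samples to permute")
    rng = np.random.default_rng(seed)
    out = np.tile(np.arange(n), (B, 1))
    return rng.permuted(out, axis=1)


def prr_pvalue(p_hat: float, perm_pvalues, smoothed: bool = False) -> float:
    """Permutation p-value: the fraction of per-iteration pivotal p-values
    strictly below the observed one, ``(1/B) #{b : p_b < p_hat}``.

    ``smoothed=True`` switches to the add-one estimator
    ``(1 + #{p_b <= p_hat}) / (1 + B)``, which avoids exact zeros for
    downstream FDR procedures but is not the default.
    """
    pv = np.asarray(perm_pvalues, dtype=float)
    if pv.size == 0:
        raise ValueError("empty permutation p-value vector")
    if not (0.0 <= p_hat <= 1.0) or pv.min() < 0.0 or pv.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    if smoothed:
        return float((1 + np.sum(pv <= p_hat)) / (1 + pv.size))
    return float(np.sum(pv < p_hat) / pv.size)


def run_prr_test(
    y,
    design: DesignSpec,
    family,
    s,
    B: int = 1000,
    seed=0,
    smoothed: bool = False,
    max_fail_frac: float = 0.10,
) -> PRRResult:
    """Full three-stage PRR test of one taxon.

    Fits the nuisance-only (reduced) model and the observed-residual model,
    computes the standard LRT p-value ``p_hat`` with df equal to the total
    number of interest columns, then refits under ``B`` row permutations of
    the residual blocks (count and zero residuals share each permutation) and
    returns the permutation p-value.  ``B=0`` skips the permutation stage and
    reports the LRT only.

    Permutation fits that do not converge are dropped and counted in
    ``n_failed`` with the denominator reduced accordingly; if more than
    ``max_fail_frac`` of them fail the taxon is reported as failed rather
    than silently biased.
    """
    family = get_family(family) if isinstance(family, str) else family
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)

    def _skipped(reason, df=0):
        return PRRResult(
            p_hat=None, p_perm=None, perm_pvalues=np.array([]), df=df, B=B,
            seed=_seed_int(seed), converged=False, skip_reason=reason,
        )

    if not np.any(y > 0):
        return _skipped("all-zero taxon")

    zi = family.zero_inflated
    rd = residualize(design.X_interest, design.X_nuisance)
    X_resid = rd.X_resid
    Z_resid = None
    if zi and design.Z_interest is not None:
        if design.Z_nuisance is None:
            raise DesignError("zero-component interest block without a nuisance block")
        rdz = residualize(design.Z_interest, design.Z_nuisance)
        Z_resid = rdz.X_resid
        rd.Z_resid, rd.Sigma_hat_Z = rdz.X_resid, rdz.Sigma_hat

    p = X_resid.shape[1]
    s_cols = 0 if Z_resid is None else Z_resid.shape[1]
    df = p + s_cols

    X_red = design.X_nuisance
    Z_red = design.Z_nuisance if zi else None
    if zi and Z_red is None:
        raise DesignError(f"{family.name} requires a zero-component nuisance block")

    fit_red = fit_ml(family, y, X_red, Z_red, s=s)
    if not fit_red.converged:
        return _skipped("reduced model did not converge", df=df)

    def full_design(x_resid_rows, z_resid_rows):
        X0 = np.hstack([x_resid_rows, X_red])
        Z0 = None
        if zi:
            Z0 = np.hstack([z_resid_rows, Z_red]) if s_cols else Z_red
        return X0, Z0

    def full_init(from_reduced: FitResult):
        """Reduced-fit parameters padded with zeros for the interest blocks."""
        parts = [np.zeros(p), from_reduced.alpha]
        if zi:
            parts += [np.zeros(s_cols), from_reduced.beta]
        if family.n_aux:
            parts.append(from_reduced.aux)
        return np.concatenate(parts)

    X0, Z0 = full_design(X_resid, Z_resid)
    fit0 = fit_ml(family, y, X0, Z0, s=s, init=full_init(fit_red))
    if not fit0.converged:
        return _skipped("observed-residual model did not converge", df=df)

    p_hat = lrt_pvalue(fit0.loglik, fit_red.loglik, df)
    result = PRRResult(
        p_hat=p_hat, p_perm=None, perm_pvalues=np.array([]), df=df, B=B,
        seed=_seed_int(seed), converged=True,
        fit_full=fit0, fit_reduced=fit_red,
    )
    if B == 0:
        return result

    perms = permutation_indices(len(y), B, seed)
    warm = fit0.params  # same layout as the permuted-design parameter vector
    perm_pvalues = []
    n_failed = 0
    for b in range(B):
        idx = perms[b]
        Xb, Zb = full_design(
            X_resid[idx], None if Z_resid is None else Z_resid[idx]
        )
        fit_b = fit_ml(family, y, Xb, Zb, s=s, init=warm)
        if not fit_b.converged:
            n_failed += 1
            continue
        perm_pvalues.append(lrt_pvalue(fit_b.loglik, fit_red.loglik, df))

    result.n_failed = n_failed
    result.perm_pvalues = np.asarray(perm_pvalues)
    if n_failed > max_fail_frac * B:
        result.converged = False
        result.skip_reason = (
            f"{n_failed}/{B} permutation fits failed (> {max_fail_frac:.0%})"
        )
        return result
    result.p_perm = prr_pvalue(p_hat, result.perm_pvalues, smoothed=smoothed)
    return result


def _seed_int(seed) -> Optional[int]:
    try:
        return int(seed)
    except (TypeError, ValueError):
        return None


# -- table-level driver ------------------------------------------------------


def _taxon_seed(master_seed: int, j: int) -> int:
    """Deterministic per-taxon seed, independent of worker count."""
    ss = np.random.SeedSequence([int(master_seed), int(j)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def run_prr_table(
    table,
    design: DesignSpec,
    families,
    B: int = 1000,
    seed: int = 0,
    smoothed: bool = False,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run the PRR test for every taxon x family combination.

    Returns a tidy frame with one row per taxon x family: ``taxon_id,
    family, df, p_lrt, p_perm, n_failed, converged, skip_reason``.  Taxa are
    embarrassingly parallel; per-taxon seeds are pre-assigned from the master
    seed so results do not depend on the worker count.
    """
    from joblib import Parallel, delayed

    if isinstance(families, (str, FamilySpec)):
        families = [families]
    families = [get_family(f) if isinstance(f, str) else f for f in families]
    s = np.asarray(table.library_sizes, dtype=float)

    def one(j, fam):
        try:
            res = run_prr_test(
                table.column(j), design, fam, s, B=B,
                seed=_taxon_seed(seed, j), smoothed=smoothed,
            )
        except Exception as exc:  # record per-taxon failures, keep running
            return {
                "taxon_id": table.taxon_ids[j],
                "family": fam.name,
                "df": 0,
                "p_lrt": np.nan,
                "p_perm": np.nan,
                "n_failed": 0,
                "converged": False,
                "skip_reason": f"error: {exc}",
            }
        return {
            "taxon_id": table.taxon_ids[j],
            "family": fam.name,
            "df": res.df,
            "p_lrt": np.nan if res.p_hat is None else res.p_hat,
            "p_perm": np.nan if res.p_perm is None else res.p_perm,
            "n_failed": res.n_failed,
            "converged": res.converged,
            "skip_reason": "" if res.skip_reason is None else res.skip_reason,
        }

    jobs = [(j, fam) for fam in families for j in range(table.n_taxa)]
    if n_jobs == 1:
        rows = [one(j, fam) for j, fam in jobs]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(one)(j, fam) for j, fam in jobs)
    return pd.DataFrame(rows)
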