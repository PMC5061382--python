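"""Gaussian additive models with penalized splines, tensor-product smooths
and penalized random intercepts, plus the stepwise term-selection and
model-criticism procedures used for the plausibility analysis.

The model is a penalized least-squares fit

    y = X beta + e,   beta_hat = argmin ||y - X beta||^2 + sum_j l_j beta' S_j beta

where the design stacks an intercept, linear covariate columns, centered
B-spline bases for one-variable smooths (second-order difference penalty
plus a null-space shrinkage penalty, so a smooth can be penalized away
entirely), row-wise-Kronecker tensor-product bases for two-variable
smooths (one penalty per margin plus shrinkage), and factor indicator
columns with identity penalty for random intercepts.  The smoothing
parameters ``l_j`` are selected by minimizing GCV via deterministic
coordinate descent on a log grid.  Inference uses the Bayesian posterior
covariance ``sigma^2 (X'X + S)^{-1}``: t-tests for linear terms,
rank-truncated chi-square Wald tests for smooth blocks, and chi-square
likelihood-ratio tests on effective-degrees-of-freedom differences for
nested model comparisons (a documented approximation for penalized fits).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

from plauscomp.errors import EstimationError, InputError

__all__ = [
    "SmoothTerm",
    "TensorTerm",
    "LinearInteraction",
    "ModelSpec",
    "GaussianGAM",
    "fit_gam",
    "likelihood_ratio_test",
    "build_baseline",
    "stepwise_select",
    "criticize",
    "StepwiseTrace",
    "CriticismReport",
]


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothTerm:
    """One-variable penalized spline ``s(var)``."""

    var: str
    n_basis: int = 10

    @property
    def name(self) -> str:
        return f"s({self.var})"


@dataclass(frozen=True)
class TensorTerm:
    """Tensor-product smooth of two variables.

    With ``interaction_only=False`` this is a full ``te(var1, var2)``
    surface (subsumes both mains; only the intercept is constrained out).
    With ``interaction_only=True`` it is the interaction-specific component
    ``ti(var1, var2)``: both marginal main-effect directions are
    constrained out, so the term is meant to sit alongside the marginal
    smooths — the triple ``s(v1) + s(v2) + ti(v1, v2)`` is the standard
    decomposition of a full tensor surface, and adding ``ti`` to a model
    that already has the mains yields an exactly nested comparison.
    """

    var1: str
    var2: str
    n_basis: int = 5  # per margin
    interaction_only: bool = False

    @property
    def name(self) -> str:
        tag = "ti" if self.interaction_only else "te"
        return f"{tag}({self.var1},{self.var2})"

    @property
    def vars(self) -> tuple[str, str]:
        return (self.var1, self.var2)


@dataclass(frozen=True)
class LinearInteraction:
    """Plain product interaction ``var1:var2`` (used in model criticism)."""

    var1: str
    var2: str

    @property
    def name(self) -> str:
        return f"{self.var1}:{self.var2}"


@dataclass(frozen=True)
class ModelSpec:
    """Terms of one additive model.

    ``linear`` are covariate names entering as plain columns; ``random``
    are grouping-factor column names fitted as penalized (random)
    intercepts.  Tensor smooths subsume the main effects of their two
    variables, so a variable inside a tensor need not appear elsewhere.
    """

    response: str
    linear: tuple = ()
    smooths: tuple = ()
    tensors: tuple = ()
    interactions: tuple = ()
    random: tuple = ()

    def __post_init__(self) -> None:
        names = self.term_names()
        if len(set(names)) != len(names):
            raise InputError(f"duplicate terms in model spec: {names}")

    def term_names(self) -> list:
        return (
            list(self.linear)
            + [t.name for t in self.interactions]
            + [t.name for t in self.smooths]
            + [t.name for t in self.tensors]
        )

    def variables(self) -> set:
        out = set(self.linear) | set(self.random) | {self.response}
        for t in self.smooths:
            out.add(t.var)
        for t in self.tensors:
            out.update(t.vars)
        for t in self.interactions:
            out.update((t.var1, t.var2))
        return out

    # -- functional updates ------------------------------------------------
    def add_linear(self, var: str) -> "ModelSpec":
        return replace(self, linear=self.linear + (var,))

    def drop_linear(self, var: str) -> "ModelSpec":
        return replace(self, linear=tuple(v for v in self.linear if v != var))

    def add_smooth(self, term: SmoothTerm) -> "ModelSpec":
        return replace(self, smooths=self.smooths + (term,))

    def drop_smooth(self, var: str) -> "ModelSpec":
        return replace(self, smooths=tuple(t for t in self.smooths if t.var != var))

    def add_tensor(self, term: TensorTerm) -> "ModelSpec":
        return replace(self, tensors=self.tensors + (term,))

    def drop_tensor(self, name: str) -> "ModelSpec":
        return replace(self, tensors=tuple(t for t in self.tensors if t.name != name))

    def add_interaction(self, term: LinearInteraction) -> "ModelSpec":
        return replace(self, interactions=self.interactions + (term,))

    def absorb_mains(self, *vars: str) -> "ModelSpec":
        """Remove linear and smooth main effects of ``vars`` (used when a
        tensor interaction subsumes them)."""
        spec = self
        for v in vars:
            spec = spec.drop_linear(v).drop_smooth(v)
        return spec


# --------------------------------------------------------------------------
# basis builders
# --------------------------------------------------------------------------

class _BSplineBasis:
    """Cubic B-spline basis with interior knots at data quantiles.

    Quantile placement spends the basis's resolution where the data are,
    which matters for heavily skewed covariates; if the quantiles collide
    (many ties), the knots fall back to a uniform grid over the range.
    """

    def __init__(self, x: np.ndarray, n_basis: int, degree: int = 3):
        x = np.asarray(x, dtype=np.float64)
        lo, hi = float(np.min(x)), float(np.max(x))
        if not np.isfinite([lo, hi]).all() or hi <= lo:
            raise EstimationError("cannot build spline basis on a constant variable")
        n_interior = n_basis - degree - 1
        if n_interior < 0:
            raise InputError(f"n_basis={n_basis} too small for degree {degree}")
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, probs)
        if n_interior and (
            len(np.unique(interior)) < n_interior
            or interior[0] <= lo or interior[-1] >= hi
        ):
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        self.knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        self.degree = degree
        self.n_basis = n_basis
        self.lo, self.hi = lo, hi

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=np.float64), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _nullspace_penalty(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Projection onto the penalty null space (the shrinkage penalty)."""
    w, U = np.linalg.eigh(S)
    U0 = U[:, w < tol * max(w.max(), 1.0)]
    return U0 @ U0.T


def _center_constraint(B: np.ndarray):
    """Sum-to-zero constraint: returns (Z, Bc) with ``Bc = B Z`` orthogonal
    to the intercept."""
    c = B.sum(axis=0, keepdims=True)
    Z = linalg.null_space(c)
    return Z, B @ Z


class _Block:
    """One design block: columns, penalties, and a transform for new data."""

    def __init__(self, name: str, kind: str, X: np.ndarray, penalties: list,
                 transform):
        self.name = name
        self.kind = kind  # linear | interaction | smooth | tensor | random
        self.X = X
        self.penalties = penalties  # list of (q x q) matrices
        self.transform = transform  # table -> (n_new x q) array


def _build_blocks(frame: pd.DataFrame, spec: ModelSpec) -> list:
    blocks: list[_Block] = []
    blocks.append(
        _Block("(Intercept)", "intercept", np.ones((len(frame), 1)), [],
               lambda tbl: np.ones((len(tbl), 1)))
    )
    for var in spec.linear:
        x = frame[var].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            raise EstimationError(f"rank-deficient design: linear term {var!r} is constant")
        blocks.append(
            _Block(var, "linear", x[:, None], [],
                   lambda tbl, v=var: tbl[v].to_numpy(dtype=np.float64)[:, None])
        )
    for term in spec.interactions:
        x = (frame[term.var1] * frame[term.var2]).to_numpy(dtype=np.float64)
        blocks.append(
            _Block(term.name, "interaction", x[:, None], [],
                   lambda tbl, t=term: (tbl[t.var1] * tbl[t.var2]).to_numpy(
                       dtype=np.float64)[:, None])
        )
    for term in spec.smooths:
        try:
            basis = _BSplineBasis(frame[term.var].to_numpy(), term.n_basis)
        except EstimationError as exc:
            raise EstimationError(f"term {term.name}: {exc}") from exc
        B = basis.transform(frame[term.var].to_numpy())
        Z, Bc = _center_constraint(B)
        S = Z.T @ _difference_penalty(term.n_basis) @ Z
        penalties = [S, _nullspace_penalty(S)]
        blocks.append(
            _Block(term.name, "smooth", Bc, penalties,
                   lambda tbl, b=basis, z=Z, t=term: b.transform(
                       tbl[t.var].to_numpy()) @ z)
        )
    for term in spec.tensors:
        try:
            b1 = _BSplineBasis(frame[term.var1].to_numpy(), term.n_basis)
            b2 = _BSplineBasis(frame[term.var2].to_numpy(), term.n_basis)
        except EstimationError as exc:
            raise EstimationError(f"term {term.name}: {exc}") from exc

        def tensor_design(tbl, b1=b1, b2=b2, t=term):
            B1 = b1.transform(tbl[t.var1].to_numpy())
            B2 = b2.transform(tbl[t.var2].to_numpy())
            return np.einsum("ij,ik->ijk", B1, B2).reshape(len(tbl), -1)

        T = tensor_design(frame)
        k1, k2 = b1.n_basis, b2.n_basis
        if term.interaction_only:
            # remove both marginal main-effect directions: coefficients
            # must satisfy sum_j c_ij m2_j = 0 per i and sum_i c_ij m1_i = 0
            # per j, with m the mean marginal basis activations
            m1 = b1.transform(frame[term.var1].to_numpy()).mean(axis=0)
            m2 = b2.transform(frame[term.var2].to_numpy()).mean(axis=0)
            C = np.vstack([np.kron(np.eye(k1), m2), np.kron(m1, np.eye(k2))])
            Z = linalg.null_space(C)
            Tc = T @ Z
        else:
            Z, Tc = _center_constraint(T)
        S1 = np.kron(_difference_penalty(k1), np.eye(k2))
        S2 = np.kron(np.eye(k1), _difference_penalty(k2))
        P1, P2 = Z.T @ S1 @ Z, Z.T @ S2 @ Z
        penalties = [P1, P2, _nullspace_penalty(P1 + P2)]
        blocks.append(
            _Block(term.name, "tensor", Tc, penalties,
                   lambda tbl, f=tensor_design, z=Z: f(tbl) @ z)
        )
    for factor in spec.random:
        levels = sorted(pd.unique(frame[factor].astype(str)))
        index = {lv: i for i, lv in enumerate(levels)}

        def indicator(tbl, idx=index, f=factor):
            X = np.zeros((len(tbl), len(idx)))
            for i, lv in enumerate(tbl[f].astype(str)):
                j = idx.get(lv)
                if j is not None:
                    X[i, j] = 1.0
            return X

        blocks.append(
            _Block(f"re({factor})", "random", indicator(frame), [np.eye(len(levels))],
                   indicator)
        )
    return blocks


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

_RHO_GRID = np.linspace(-12.0, 12.0, 9)


class GaussianGAM(BaseEstimator, RegressorMixin):
    """Penalized-spline additive model for a Gaussian response.

    Parameters
    ----------
    spec : ModelSpec
        Terms of the model.
    n_sweeps : int
        Coordinate-descent sweeps for GCV smoothing-parameter selection.
    gcv_gamma : float
        Inflation of the effective-df cost in the GCV score.  Plain GCV
        (gamma = 1) is prone to undersmoothing, which makes model
        comparisons anti-conservative; gamma = 1.4 is the standard remedy.

    Attributes (after ``fit``)
    --------------------------
    coef_, edf_, aic_, loglik_, sigma2_, deviance_explained_,
    fitted_values_, residuals_, terms_ (per-term statistics),
    lambda_ (selected smoothing parameters), n_obs_
    """

    def __init__(self, spec: ModelSpec, n_sweeps: int = 3, gcv_gamma: float = 1.4):
        self.spec = spec
        self.n_sweeps = n_sweeps
        self.gcv_gamma = gcv_gamma

    # factor blocks with more levels than this are solved by Schur
    # complement against their diagonal normal-equation block
    _PARTITION_MIN_LEVELS = 40

    # -- internals ---------------------------------------------------------
    def _assemble(self, frame: pd.DataFrame):
        blocks = _build_blocks(frame, self.spec)
        # move the largest random-intercept block last so its diagonal
        # normal-equation block can be eliminated cheaply
        big = [
            (b.X.shape[1], i)
            for i, b in enumerate(blocks)
            if b.kind == "random" and b.X.shape[1] >= self._PARTITION_MIN_LEVELS
        ]
        self._partitioned_ = bool(big)
        if big:
            _, idx = max(big)
            blocks = blocks[:idx] + blocks[idx + 1:] + [blocks[idx]]
        X = np.hstack([b.X for b in blocks])
        slices, pos = [], 0
        for b in blocks:
            q = b.X.shape[1]
            slices.append(slice(pos, pos + q))
            pos += q
        return blocks, X, slices

    def fit(self, frame: pd.DataFrame, y=None) -> "GaussianGAM":
        missing = self.spec.variables() - set(frame.columns)
        if missing:
            raise InputError(f"table lacks variables: {sorted(missing)}")
        frame = frame.reset_index(drop=True)
        yv = frame[self.spec.response].to_numpy(dtype=np.float64)
        n = len(yv)
        n_smooth = len(self.spec.smooths) + len(self.spec.tensors)
        if n_smooth and n < 10 * n_smooth:
            raise EstimationError(
                f"{n} rows is too few for {n_smooth} smooth terms (need >= 10 each)"
            )
        blocks, X, slices = self._assemble(frame)
        p = X.shape[1]
        XtX = X.T @ X
        Xty = X.T @ yv
        yty = float(yv @ yv)

        # penalties normalized so unit lambda is comparable across terms;
        # stored as (slice, scaled matrix) rather than p x p embeddings
        pen_entries, pen_labels = [], []
        for b, sl in zip(blocks, slices):
            tr_block = max(np.trace(XtX[sl, sl]), 1e-12)
            for j, S in enumerate(b.penalties):
                tr_s = np.trace(S)
                scale = tr_block / tr_s if tr_s > 0 else 1.0
                pen_entries.append((sl, S * scale))
                pen_labels.append(f"{b.name}[{j}]")
        jitter = 1e-10 * (np.trace(XtX) / p + 1.0)

        def penalized_fit(rho: np.ndarray):
            A = XtX.copy()
            for r, (sl, S) in zip(rho, pen_entries):
                A[sl, sl] += math.exp(r) * S
            A[np.diag_indices_from(A)] += jitter
            try:
                c, low = linalg.cho_factor(A)
            except linalg.LinAlgError as exc:
                raise EstimationError(
                    "rank-deficient design; offending terms may include: "
                    + ", ".join(self.spec.term_names())
                ) from exc
            beta = linalg.cho_solve((c, low), Xty)
            F = linalg.cho_solve((c, low), XtX)
            edf_vec = np.diag(F).copy()
            rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-12)
            return beta, edf_vec, rss, (c, low)

        # fast path: eliminate the trailing random-intercept block (whose
        # normal-equation block is diagonal) by Schur complement, so GCV
        # evaluation costs O(pf^2 (pf + pr)) instead of O(p^3)
        if getattr(self, "_partitioned_", False):
            pr = blocks[-1].X.shape[1]
            pf = p - pr
            Ff = XtX[:pf, :pf]
            Bm = XtX[:pf, pf:]
            cdiag = np.diag(XtX)[pf:].copy()
            bf, br = Xty[:pf], Xty[pf:]
            # the partitioned factor owns exactly the last penalty entry
            dense_pen = pen_entries[:-1]
            _, S_last = pen_entries[-1]
            s_r = float(S_last[0, 0])  # scaled identity

            def fast_edf_rss(rho: np.ndarray):
                Af = Ff.copy()
                for r, (sl, S) in zip(rho[:-1], dense_pen):
                    Af[sl, sl] += math.exp(r) * S
                d = cdiag + math.exp(rho[-1]) * s_r + jitter
                Af[np.diag_indices_from(Af)] += jitter
                Bd = Bm / d
                Sc = Af - Bd @ Bm.T
                try:
                    ch = linalg.cho_factor(Sc)
                except linalg.LinAlgError as exc:
                    raise EstimationError(
                        "rank-deficient design; offending terms may include: "
                        + ", ".join(self.spec.term_names())
                    ) from exc
                beta_f = linalg.cho_solve(ch, bf - Bd @ br)
                beta_r = (br - Bm.T @ beta_f) / d
                M1 = linalg.cho_solve(ch, Ff - Bd @ Bm.T)
                W = linalg.cho_solve(ch, Bm)
                g = np.einsum("ij,ij->j", Bm, W)
                cr = cdiag / d
                edf = float(np.trace(M1)) + float(np.sum(cr + g * (cr - 1.0) / d))
                xb_f = Ff @ beta_f + Bm @ beta_r
                xb_r = Bm.T @ beta_f + cdiag * beta_r
                rss = max(
                    yty - 2 * (beta_f @ bf + beta_r @ br)
                    + beta_f @ xb_f + beta_r @ xb_r,
                    1e-12,
                )
                return edf, rss

            def gcv(r):
                edf, rss = fast_edf_rss(r)
                return n * rss / max(n - self.gcv_gamma * edf, 1e-3) ** 2
        else:
            def gcv(r):
                _, edf_vec, rss, _ = penalized_fit(r)
                edf = edf_vec.sum()
                return n * rss / max(n - self.gcv_gamma * edf, 1e-3) ** 2

        n_pen = len(pen_entries)
        rho = np.zeros(n_pen)
        if n_pen:
            best = gcv(rho)
            for _ in range(self.n_sweeps):
                improved = False
                for j in range(n_pen):
                    for cand in _RHO_GRID:
                        trial = rho.copy()
                        trial[j] = cand
                        score = gcv(trial)
                        if score < best - 1e-12:
                            best, rho, improved = score, trial, True
                if not improved:
                    break

        beta, edf_vec, rss, chol = penalized_fit(rho)
        edf = float(edf_vec.sum())
        sigma2 = rss / max(n - edf, 1.0)
        Vb = sigma2 * linalg.cho_solve(chol, np.eye(p))

        self.blocks_ = blocks
        self.slices_ = slices
        self.coef_ = beta
        self.edf_vector_ = edf_vec
        self.edf_ = edf
        self.sigma2_ = float(sigma2)
        self.rss_ = float(rss)
        self.n_obs_ = n
        self.lambda_ = {lab: math.exp(r) for lab, r in zip(pen_labels, rho)}
        self.loglik_ = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * (edf + 1.0)
        self.fitted_values_ = X @ beta
        self.residuals_ = yv - self.fitted_values_
        tss = float(np.sum((yv - yv.mean()) ** 2))
        self.deviance_explained_ = 1.0 - rss / tss if tss > 0 else float("nan")
        self.frame_ = frame
        self._compute_term_stats(Vb)
        return self

    def _compute_term_stats(self, Vb: np.ndarray) -> None:
        df_resid = max(self.n_obs_ - self.edf_, 1.0)
        terms = []
        for b, sl in zip(self.blocks_, self.slices_):
            beta_b = self.coef_[sl]
            edf_b = float(self.edf_vector_[sl].sum())
            entry: dict = {"name": b.name, "kind": b.kind, "edf": edf_b}
            if b.kind in ("intercept", "linear", "interaction"):
                se = math.sqrt(max(Vb[sl, sl][0, 0], 1e-300))
                t = beta_b[0] / se
                entry.update(
                    estimate=float(beta_b[0]),
                    se=se,
                    t=float(t),
                    p=float(2 * stats.t.sf(abs(t), df_resid)),
                )
            else:
                V = Vb[sl, sl]
                r = max(1, int(round(edf_b)))
                w, U = np.linalg.eigh(V)
                order = np.argsort(w)[::-1][:r]
                w_r, U_r = w[order], U[:, order]
                good = w_r > 1e-12 * max(w_r.max(), 1e-300)
                z = U_r[:, good].T @ beta_b
                stat = float(np.sum(z**2 / w_r[good]))
                entry.update(
                    stat=stat,
                    test_df=int(np.sum(good)),
                    p=float(stats.chi2.sf(stat, max(int(np.sum(good)), 1))),
                )
            terms.append(entry)
        self.terms_ = terms

    def term_pvalues(self, include_random: bool = False) -> dict:
        return {
            t["name"]: t["p"]
            for t in self.terms_
            if t["kind"] != "intercept" and (include_random or t["kind"] != "random")
        }

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        X = np.hstack([b.transform(frame) for b in self.blocks_])
        return X @ self.coef_

    def summary(self) -> str:
        """Two-block report: linear coefficients, then smooth terms."""
        lines = [f"Gaussian additive model: {self.spec.response}",
                 f"n = {self.n_obs_}, edf = {self.edf_:.2f}, "
                 f"AIC = {self.aic_:.2f}, deviance explained = "
                 f"{self.deviance_explained_:.3f}", "",
                 "Linear coefficients", "-" * 60,
                 f"{'term':<28}{'est':>9}{'se':>8}{'t':>8}{'p':>9}"]
        for t in self.terms_:
            if t["kind"] in ("intercept", "linear", "interaction"):
                lines.append(
                    f"{t['name']:<28}{t['estimate']:>9.3f}{t['se']:>8.3f}"
                    f"{t['t']:>8.2f}{t['p']:>9.2g}"
                )
        lines += ["", "Smooth terms", "-" * 60,
                  f"{'term':<28}{'edf':>8}{'chi2':>9}{'p':>9}"]
        for t in self.terms_:
            if t["kind"] in ("smooth", "tensor", "random"):
                lines.append(
                    f"{t['name']:<28}{t['edf']:>8.2f}{t.get('stat', float('nan')):>9.2f}"
                    f"{t.get('p', float('nan')):>9.2g}"
                )
        return "\n".join(lines)


def fit_gam(frame: pd.DataFrame, spec: ModelSpec) -> GaussianGAM:
    """Fit one Gaussian additive model (thin wrapper over the estimator)."""
    return GaussianGAM(spec).fit(frame)


# --------------------------------------------------------------------------
# nested-model comparison
# --------------------------------------------------------------------------

def likelihood_ratio_test(small: GaussianGAM, big: GaussianGAM) -> dict:
    """Chi-square LRT between nested penalized fits on the same rows.

    The statistic is the Gaussian profile-likelihood ratio (clipped at 0).
    The reference degrees of freedom is the *parametric* (coefficient-count)
    difference, not the effective-df difference: because the penalized fit
    of the larger model can only lie below its unpenalized fit, the
    chi-square with the full coefficient-count df is a valid, conservative
    reference even though the smoothing parameters were data-selected.
    (The effective-df difference is reported alongside for diagnostics;
    using it as the reference df is markedly anti-conservative once GCV has
    picked the wiggliness.)
    """
    if small.n_obs_ != big.n_obs_:
        raise InputError("LRT requires models fitted to the same rows")
    stat = max(0.0, 2.0 * (big.loglik_ - small.loglik_))
    df_param = max(len(big.coef_) - len(small.coef_), 1)
    return {
        "stat": stat,
        "df": df_param,
        "edf_df": big.edf_ - small.edf_,
        "p": float(stats.chi2.sf(stat, df_param)),
    }


# --------------------------------------------------------------------------
# baseline construction
# --------------------------------------------------------------------------

def analysis_frame(table: pd.DataFrame, variables: set | None = None) -> pd.DataFrame:
    """Rows usable for modelling: not flagged excluded, no NaN in the
    requested variables."""
    frame = table
    if "excluded" in frame.columns:
        frame = frame[~frame["excluded"].astype(bool)]
    if variables:
        cols = [c for c in variables if c in frame.columns]
        frame = frame.dropna(subset=cols)
    return frame.reset_index(drop=True)


def collinearity_screen(
    table: pd.DataFrame, candidates: list, threshold: float = 0.6
) -> tuple[list, list]:
    """Greedy screen: walk the candidates in order, dropping any covariate
    whose absolute correlation with an already-retained one exceeds the
    threshold.  Returns (kept, dropped-with-reasons)."""
    kept: list = []
    dropped: list = []
    for var in candidates:
        partner = None
        for other in kept:
            r = float(np.corrcoef(table[var], table[other])[0, 1])
            if abs(r) > threshold:
                partner = (other, r)
                break
        if partner is None:
            kept.append(var)
        else:
            dropped.append({"term": var, "correlated_with": partner[0],
                            "r": partner[1]})
    return kept, dropped


def build_baseline(
    table: pd.DataFrame,
    candidates: list,
    random_factors: tuple = ("modifier", "head"),
    response: str = "rating",
    alpha: float = 0.05,
    collinearity_threshold: float = 0.6,
    max_rounds: int = 30,
) -> tuple[GaussianGAM, dict]:
    """Covariate baseline: all candidate linear terms plus random intercepts,
    iteratively pruned by Wald tests and counter-checked by LRTs.

    A collinearity screen first removes covariates correlated beyond the
    threshold with a retained one.  Then the least significant linear term
    with Wald p >= alpha is dropped and the model refitted, until all
    remaining linear terms are significant.  The result is then verified by
    LRT — no dropped term should significantly improve the model when
    re-added, and every kept term should significantly worsen it when
    removed; outcomes (including violations) are recorded in the trace.
    Random intercepts are always retained.
    """
    needed = set(candidates) | set(random_factors) | {response}
    frame = analysis_frame(table, needed)
    # a covariate with no variation in the usable rows cannot enter the design
    constant = [v for v in candidates if float(np.ptp(frame[v])) == 0.0]
    usable = [v for v in candidates if v not in constant]
    kept, screened_out = collinearity_screen(frame, usable,
                                             collinearity_threshold)
    trace: dict = {"constant_dropped": constant,
                   "collinearity_dropped": screened_out, "wald_steps": [],
                   "lrt_readd": [], "lrt_removal": []}
    dropped = [d["term"] for d in screened_out]

    def fit_linear(terms: list) -> GaussianGAM:
        spec = ModelSpec(response=response, linear=tuple(terms),
                         random=tuple(random_factors))
        return GaussianGAM(spec).fit(frame)

    model = fit_linear(kept)
    for _ in range(max_rounds):
        # Wald pruning: drop the weakest non-significant linear term
        pvals = {t["name"]: t["p"] for t in model.terms_ if t["kind"] == "linear"}
        weak = {k: v for k, v in pvals.items() if v >= alpha}
        if not weak:
            break
        victim = max(weak, key=weak.get)
        trace["wald_steps"].append({"dropped": victim, "p": weak[victim]})
        kept.remove(victim)
        dropped.append(victim)
        model = fit_linear(kept)
    # counter-check (recorded): no dropped term should help when re-added,
    # every kept term should hurt when removed
    violations: list = []
    for var in dropped:
        bigger = fit_linear(kept + [var])
        res = likelihood_ratio_test(model, bigger)
        trace["lrt_readd"].append({"term": var, **res})
        if res["p"] < alpha:
            violations.append({"term": var, "check": "readd", "p": res["p"]})
    for var in list(kept):
        smaller = fit_linear([v for v in kept if v != var])
        res = likelihood_ratio_test(smaller, model)
        trace["lrt_removal"].append({"term": var, **res})
        if res["p"] >= alpha:
            violations.append({"term": var, "check": "removal", "p": res["p"]})
    trace["verification_violations"] = violations
    trace["final_linear_terms"] = list(kept)
    return model, trace


# --------------------------------------------------------------------------
# stepwise selection of measure terms
# --------------------------------------------------------------------------

@dataclass
class StepwiseStep:
    candidates: list  # dicts: term, stat, df, p, aic
    accepted: str | None
    aic_before: float
    aic_after: float


@dataclass
class StepwiseTrace:
    steps: list = field(default_factory=list)

    def accepted_terms(self) -> list:
        return [s.accepted for s in self.steps if s.accepted]


def _candidate_specs(
    current: ModelSpec,
    included: set,
    measures: list,
    pair_freq_var: str,
    offer_linear_mains: bool,
):
    """Enumerate (label, spec) candidates for one stepwise step.

    Interaction candidates are interaction-specific tensor components
    (``ti``) added alongside the already-included marginal smooths, so
    every comparison is exactly nested; mains + ti jointly represent the
    full tensor surface.
    """
    existing = {frozenset(t.vars) for t in current.tensors}
    out = []
    for m in measures:
        if m in included:
            continue
        out.append((f"s({m})", current.add_smooth(SmoothTerm(m))))
        if offer_linear_mains:
            out.append((m, current.add_linear(m)))
    for mi, mj in itertools.combinations(sorted(included), 2):
        if frozenset((mi, mj)) in existing:
            continue
        term = TensorTerm(mi, mj, interaction_only=True)
        out.append((term.name, current.add_tensor(term)))
    for mi in sorted(included):
        if frozenset((mi, pair_freq_var)) in existing:
            continue
        term = TensorTerm(mi, pair_freq_var, interaction_only=True)
        out.append((term.name, current.add_tensor(term)))
    return out


def stepwise_select(
    table: pd.DataFrame,
    baseline: GaussianGAM,
    measures: list,
    pair_freq_var: str = "log_pair_freq",
    alpha: float = 0.05,
    offer_linear_mains: bool = False,
    max_steps: int = 12,
) -> tuple[GaussianGAM, StepwiseTrace]:
    """Forward stepwise selection of plausibility-measure terms.

    Each step offers smooth main effects of measures not yet included,
    tensor interactions among included measures, and tensor interactions of
    included measures with pair frequency.  A candidate is acceptable when
    its LRT against the current model has p < alpha and its AIC improves;
    among acceptable candidates the lowest AIC wins.  Interactions enter as
    interaction-specific tensor components next to the retained marginal
    smooths (together they form the full tensor surface), which keeps every
    model comparison exactly nested.  The procedure is order-free: all
    candidates are tested at every step.

    ``offer_linear_mains`` additionally offers each measure as a plain
    linear term.  Off by default: the shrinkage-spline basis already
    contains the linear trend, so the extra candidates only enlarge the
    family of null tests per step (measurably inflating spurious
    inclusions) without adding expressiveness.
    """
    needed = baseline.spec.variables() | set(measures) | {pair_freq_var}
    frame = analysis_frame(table, needed)
    current = GaussianGAM(baseline.spec).fit(frame)
    included: set = set()
    trace = StepwiseTrace()

    for _ in range(max_steps):
        cands = _candidate_specs(current.spec, included, measures,
                                 pair_freq_var, offer_linear_mains)
        if not cands:
            break
        records, fits = [], {}
        for label, spec in cands:
            try:
                fit = GaussianGAM(spec).fit(frame)
            except EstimationError:
                continue
            res = likelihood_ratio_test(current, fit)
            records.append({"term": label, **res, "aic": fit.aic_})
            fits[label] = fit
        acceptable = [
            r for r in records if r["p"] < alpha and r["aic"] < current.aic_
        ]
        if not acceptable:
            trace.steps.append(StepwiseStep(records, None, current.aic_,
                                            current.aic_))
            break
        winner = min(acceptable, key=lambda r: r["aic"])
        new_model = fits[winner["term"]]
        trace.steps.append(
            StepwiseStep(records, winner["term"], current.aic_, new_model.aic_)
        )
        current = new_model
        for t in current.spec.tensors:
            included.update(v for v in t.vars if v in measures)
        for t in current.spec.smooths:
            if t.var in measures:
                included.add(t.var)
        included.update(v for v in current.spec.linear if v in measures)
    return current, trace


# --------------------------------------------------------------------------
# model criticism
# --------------------------------------------------------------------------

@dataclass
class CriticismReport:
    outlier: dict
    linearity: list
    non_negative: dict


def _all_terms_significant(model: GaussianGAM, alpha: float) -> bool:
    return all(p < alpha for p in model.term_pvalues().values())


def criticize(
    table: pd.DataFrame,
    final: GaussianGAM,
    alpha: float = 0.05,
    sd_threshold: float = 2.5,
    min_rows: int = 50,
) -> CriticismReport:
    """Three post-fit checks on the final model.

    1. Outlier refit: drop rows whose residual exceeds ``sd_threshold``
       residual standard deviations, refit the same spec, and record
       whether every term stays significant plus both deviance-explained
       values.
    2. Linearity: for each tensor term, refit with the tensor replaced by
       linear mains plus a linear product interaction, and record the LRT
       p-value for the tensor model's superiority.
    3. Non-negativity: drop rows with negative modifier or head proximity,
       refit, and record term significance.
    """
    frame = final.frame_
    resid = final.residuals_
    sd = float(np.std(resid))
    keep = np.abs(resid) <= sd_threshold * sd
    sub = frame[keep].reset_index(drop=True)
    if len(sub) < min_rows:
        raise EstimationError(
            f"outlier refit would use {len(sub)} rows (< {min_rows}); criticism aborted"
        )
    refit = GaussianGAM(final.spec).fit(sub)
    outlier = {
        "n_removed": int((~keep).sum()),
        "all_terms_significant": _all_terms_significant(refit, alpha),
        "deviance_explained_full": final.deviance_explained_,
        "deviance_explained_refit": refit.deviance_explained_,
        "term_pvalues": refit.term_pvalues(),
    }

    linearity = []
    for term in final.spec.tensors:
        spec_lin = final.spec.drop_tensor(term.name)
        if not term.interaction_only:
            # a full tensor surface also carried the mains: restore them
            # as linear terms in the replacement model
            for v in term.vars:
                if v not in spec_lin.linear:
                    spec_lin = spec_lin.add_linear(v)
        spec_lin = spec_lin.add_interaction(LinearInteraction(term.var1, term.var2))
        lin_model = GaussianGAM(spec_lin).fit(frame)
        res = likelihood_ratio_test(lin_model, final)
        linearity.append({"term": term.name, **res,
                          "tensor_superior": res["p"] < alpha})

    non_negative: dict = {"applicable": False}
    if {"modifier_proximity", "head_proximity"} <= set(frame.columns):
        mask = (frame["modifier_proximity"] >= 0) & (frame["head_proximity"] >= 0)
        sub2 = frame[mask].reset_index(drop=True)
        if len(sub2) < min_rows:
            raise EstimationError(
                f"non-negativity refit would use {len(sub2)} rows (< {min_rows}); "
                "criticism aborted"
            )
        refit2 = GaussianGAM(final.spec).fit(sub2)
        non_negative = {
            "applicable": True,
            "n_removed": int((~mask).sum()),
            "all_terms_significant": _all_terms_significant(refit2, alpha),
            "term_pvalues": refit2.term_pvalues(),
        }
    return CriticismReport(outlier=outlier, linearity=linearity,
                           non_negative=non_negative)
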