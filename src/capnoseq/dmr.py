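"""Multivariable distance matrix regression (discrepancy analysis).

Associations between a pairwise dissimilarity matrix ``D`` and patient-level
covariates are quantified without ever embedding the sequences: the squared
dissimilarities are Gower-centered into an inner-product matrix ``G`` whose
trace is the total discrepancy ``SS_T = (1/n) sum_{i<j} d_ij^2``, and the
covariate design's hat matrix projects ``G`` into explained and residual
parts,

    pseudo-R2_total = tr(H G H) / tr(G),
    pseudo-F_total  = (SS_expl / m) / (SS_res / (n - m - 1)),

with ``m`` the model degrees of freedom excluding the intercept. Per-term
statistics use marginal (drop-one) shares: the loss of explained discrepancy
when the term's column block is removed from the full design. This
partitioning is order-invariant; shares need not sum to the total when
covariates are correlated. When ``D`` comes from Euclidean points, the total
pseudo-F on a single binary covariate is exactly the classical one-way
ANOVA F on those points.

Inference is by permutation of patient identities (rows/columns of ``D``
jointly), with the add-one correction ``p = (1 + #{F* >= F}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DesignMatrix:
    """Covariate design for distance matrix regression.

    ``X`` excludes the intercept (added internally); ``terms`` maps each
    covariate term to its column indices in ``X`` (a categorical term with
    L levels occupies L-1 reference-coded indicator columns).
    """

    ids: list[str]
    X: np.ndarray
    terms: dict[str, list[int]]
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def df(self, term: str) -> int:
        return len(self.terms[term])


@dataclass
class TermResult:
    term: str
    df: int
    pseudo_F: float
    pseudo_R2: float
    proportion_explained: float
    p_value: float | None = None


@dataclass
class DiscrepancyResult:
    """Per-term and total discrepancy-analysis statistics (the shape of a
    distance-regression summary table, with a Total row)."""

    terms: list[TermResult]
    total: TermResult
    n: int
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.term,
                "pseudo_F": t.pseudo_F,
                "pseudo_R2": t.pseudo_R2,
                "proportion_explained": t.proportion_explained,
                "p_value": t.p_value,
            }
            for t in [*self.terms, self.total]
        ]
        return pd.DataFrame(rows)


def build_design(
    covariates: pd.DataFrame,
    numeric: list[str],
    categorical: list[str],
    id_column: str = "patient_id",
) -> DesignMatrix:
    """Assemble a full-rank design from a per-patient covariate table.

    Numeric covariates are standardized (mean 0, sd 1); categoricals are
    reference-coded against their first sorted level. Patients with any
    missing value among the requested terms are dropped listwise, with the
    count recorded on the result.
    """
    cols = numeric + categorical
    work = covariates[[id_column, *cols]].copy()
    complete = work.dropna()
    n_dropped = len(work) - len(complete)
    blocks: list[np.ndarray] = []
    terms: dict[str, list[int]] = {}
    col = 0
    for name in numeric:
        x = complete[name].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        blocks.append(((x - x.mean()) / sd)[:, None])
        terms[name] = [col]
        col += 1
    for name in categorical:
        dummies = pd.get_dummies(complete[name].astype("category"), drop_first=True)
        if dummies.shape[1] == 0:
            raise ValueError(f"covariate {name!r} has a single level")
        blocks.append(dummies.to_numpy(dtype=float))
        terms[name] = list(range(col, col + dummies.shape[1]))
        col += dummies.shape[1]
    X = np.hstack(blocks)
    Xi = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
        raise ValueError(f"rank-deficient design among terms {list(terms)}")
    return DesignMatrix(
        ids=[str(i) for i in complete[id_column]], X=X, terms=terms,
        n_dropped=n_dropped,
    )


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix ``G = -1/2 J (D*D) J``.

    ``J = I - 11'/n``. ``trace(G)`` equals the total discrepancy
    ``(1/n) sum_{i<j} d_ij^2``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    A = -0.5 * D * D
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def _hat(X_with_intercept: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X_with_intercept)
    return Q @ Q.T


def _ss_explained(H: np.ndarray, G: np.ndarray) -> float:
    # tr(H G H) = tr(H G) for idempotent H; elementwise sum since symmetric
    return float(np.sum(H * G))


def mdmra_fit(
    D: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DiscrepancyResult:
    """Fit the multivariable distance matrix regression.

    Returns total and per-term (drop-one) pseudo-F, pseudo-R2, proportion of
    the explained discrepancy, and permutation p-values. With ``n_perm=0``
    only the observed statistics are computed (p-values None).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n != design.n:
        raise ValueError("D and design have different n")
    m = design.X.shape[1]
    if m == 0:
        # intercept-only model: centered G has zero projection, nothing explained
        total = TermResult("Total", 0, float("nan"), 0.0, 0.0, None)
        return DiscrepancyResult([], total, n, 0, seed)
    if n < m + 2:
        raise ValueError("too few patients for the number of model columns")
    if 0 < n_perm < 99:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")

    G = gower_center(D)
    ss_t = float(np.trace(G))
    ones = np.ones((n, 1))
    H_full = _hat(np.hstack([ones, design.X]))
    H_reduced = {
        t: _hat(np.hstack([ones, np.delete(design.X, cols, axis=1)]))
        if len(cols) < m
        else _hat(ones)
        for t, cols in design.terms.items()
    }

    def stats(Gm: np.ndarray) -> tuple[float, dict[str, float]]:
        ss_full = _ss_explained(H_full, Gm)
        ss_res = ss_t - ss_full
        denom = ss_res / (n - m - 1)
        f_total = (ss_full / m) / denom
        f_terms = {}
        for t, cols in design.terms.items():
            delta = ss_full - _ss_explained(H_reduced[t], Gm)
            f_terms[t] = (delta / len(cols)) / denom
        return f_total, f_terms

    f_total_obs, f_terms_obs = stats(G)
    ss_full_obs = _ss_explained(H_full, G)
    r2_total = ss_full_obs / ss_t if ss_t > 0 else 0.0
    term_r2 = {}
    for t in design.terms:
        delta = ss_full_obs - _ss_explained(H_reduced[t], G)
        term_r2[t] = delta / ss_t if ss_t > 0 else 0.0

    ge_total = 0
    ge_terms = dict.fromkeys(design.terms, 0)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            f_tot_p, f_terms_p = stats(Gp)
            ge_total += f_tot_p >= f_total_obs
            for t in design.terms:
                ge_terms[t] += f_terms_p[t] >= f_terms_obs[t]

    def pval(ge: int) -> float | None:
        if n_perm == 0:
            return None
        return (1 + ge) / (n_perm + 1)

    terms = [
        TermResult(
            term=t,
            df=len(cols),
            pseudo_F=f_terms_obs[t],
            pseudo_R2=term_r2[t],
            proportion_explained=(term_r2[t] / r2_total) if r2_total > 0 else 0.0,
            p_value=pval(ge_terms[t]),
        )
        for t, cols in design.terms.items()
    ]
    total = TermResult(
        term="Total", df=m, pseudo_F=f_total_obs, pseudo_R2=r2_total,
        proportion_explained=1.0 if r2_total > 0 else 0.0,
        p_value=pval(ge_total),
    )
    return DiscrepancyResult(
        terms=terms, total=total, n=n, n_permutations=n_perm, seed=seed
    )


def bivariate_dmr(
    D: np.ndarray,
    x: np.ndarray | pd.Series,
    name: str = "x",
    n_perm: int = 1000,
    seed: int | None = None,
    categorical: bool = False,
) -> DiscrepancyResult:
    """Distance matrix regression on a single covariate (intercept + x).

    Used for covariates tested outside the joint model, e.g. hypoxemia
    duration when desaturation is too rare to enter the multivariable fit.
    """
    x = np.asarray(x)
    ids = [str(i) for i in range(len(x))]
    df = pd.DataFrame({"patient_id": ids, name: x})
    design = build_design(
        df, numeric=[] if categorical else [name],
        categorical=[name] if categorical else [],
    )
    return mdmra_fit(np.asarray(D, dtype=float), design, n_perm=n_perm, seed=seed)
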