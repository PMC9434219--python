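"""Quantitative-genetic summaries: variance partition, broad-sense
heritability, genomic-BLUP genetic effects, genetic correlations, and the
Hotelling T-squared comparison of family performance.

The variance partition fits the fully random two-way model

    y_{gcr} = mu + G_g + E_c + (GxE)_{gc} + eps_{gcr}

(genotype, environment/condition, their interaction, residual).  Balanced
designs use the exact ANOVA estimators (identical to REML inside the
parameter space); unbalanced designs fall back to EM-REML.  With a single
observation per genotype x condition cell the interaction and residual are
confounded: the lumped term is reported as var_eps with var_GxE = 0 and
``gxe_confounded`` set.  Broad-sense heritability divides both terms by the
number of environments, so H^2 is unaffected by the confounding.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .panels import GenotypeMatrix, _TidyPanel


@dataclasses.dataclass
class VarianceComponents:
    """Nonnegative variance components of the G/E/GxE/residual partition."""

    var_G: float
    var_E: float
    var_GxE: float
    var_eps: float
    e: int = 1
    truncated: bool = False
    gxe_confounded: bool = False

    def __post_init__(self) -> None:
        if self.e < 1:
            raise ValueError("number of environments must be >= 1")
        for name in ("var_G", "var_E", "var_GxE", "var_eps"):
            v = getattr(self, name)
            if v < 0:
                setattr(self, name, 0.0)
                self.truncated = True


def broad_sense_h2(vc: VarianceComponents, *, conventional: bool = False) -> float:
    """Broad-sense heritability H2 = sG2 / (sG2 + sE2 + sGxE2/e + se2/e).

    The environment variance enters the denominator undivided by e (primary
    form).  ``conventional=True`` drops sE2 from the denominator, the more
    common multi-environment line-mean convention.
    """
    denom = vc.var_G + vc.var_GxE / vc.e + vc.var_eps / vc.e
    if not conventional:
        denom += vc.var_E
    if denom <= 0:
        raise ValueError("zero denominator: degenerate data")
    return vc.var_G / denom


# --------------------------------------------------------------------------
# variance partition


def _tidy_values(values, grouping=None) -> pd.DataFrame:
    """Normalize input to columns genotype, condition, value."""
    if isinstance(values, _TidyPanel):
        raise TypeError("pass a single trait's observations, not a whole panel")
    df = pd.DataFrame(values).copy()
    if {"sample_id", "condition", "value"} <= set(df.columns):
        tidy = df[["sample_id", "condition", "value"]].copy()
    else:  # wide: index = samples, columns = conditions
        tidy = df.stack().rename("value").reset_index()
        tidy.columns = ["sample_id", "condition", "value"]
    if grouping is not None:
        gmap = dict(grouping) if not isinstance(grouping, dict) else grouping
        tidy["genotype"] = tidy["sample_id"].map(gmap)
        if tidy["genotype"].isna().any():
            raise ValueError("grouping does not cover all samples")
    else:
        tidy["genotype"] = tidy["sample_id"]
    return tidy.dropna(subset=["value"])


def _anova_components(tidy: pd.DataFrame) -> VarianceComponents:
    """Exact ANOVA estimators for a balanced genotype x condition design."""
    a = tidy["genotype"].nunique()
    b = tidy["condition"].nunique()
    r = len(tidy) // (a * b)
    y = tidy["value"].to_numpy(float)
    grand = y.mean()
    gm = tidy.groupby("genotype")["value"].mean()
    cm = tidy.groupby("condition")["value"].mean()
    cellm = tidy.groupby(["genotype", "condition"])["value"].mean()

    ss_a = r * b * ((gm - grand) ** 2).sum()
    ss_b = r * a * ((cm - grand) ** 2).sum()
    cell_dev = cellm.to_frame("cell").reset_index()
    cell_dev["dev"] = (cell_dev["cell"]
                       - cell_dev["genotype"].map(gm)
                       - cell_dev["condition"].map(cm) + grand)
    ss_ab = r * (cell_dev["dev"] ** 2).sum()
    merged = tidy.merge(cellm.rename("cell"), on=["genotype", "condition"])
    ss_e = ((merged["value"] - merged["cell"]) ** 2).sum()

    ms_a = ss_a / (a - 1)
    ms_b = ss_b / (b - 1)
    ms_ab = ss_ab / ((a - 1) * (b - 1))
    if r > 1:
        ms_e = ss_e / (a * b * (r - 1))
        var_eps = ms_e
        var_gxe = (ms_ab - ms_e) / r
        confounded = False
    else:
        var_eps = ms_ab          # interaction + residual, inseparable
        var_gxe = 0.0
        confounded = True
    var_g = (ms_a - ms_ab) / (r * b)
    var_e = (ms_b - ms_ab) / (r * a)
    return VarianceComponents(var_g, var_e, var_gxe, var_eps, e=b,
                              gxe_confounded=confounded)


def _em_reml(tidy: pd.DataFrame, max_iter: int = 500, tol: float = 1e-8,
             ridge: float = 1e-10) -> VarianceComponents:
    """EM-REML for the three-random-effect model on unbalanced data."""
    geno = pd.Categorical(tidy["genotype"])
    cond = pd.Categorical(tidy["condition"])
    cell = pd.Categorical(list(zip(geno.codes, cond.codes)))
    n = len(tidy)
    y = tidy["value"].to_numpy(float)
    Zs = []
    for codes, k in ((geno.codes, len(geno.categories)),
                     (cond.codes, len(cond.categories)),
                     (cell.codes, len(cell.categories))):
        Z = np.zeros((n, k))
        Z[np.arange(n), codes] = 1.0
        Zs.append(Z)
    has_reps = len(cell.categories) < n
    ones = np.ones((n, 1))
    sig = np.array([y.var(ddof=1) / 4.0] * 4) + ridge
    if not has_reps:
        sig[2] = 0.0  # interaction confounded with residual
    qs = [Z.shape[1] for Z in Zs]
    for _ in range(max_iter):
        V = sig[3] * np.eye(n)
        for k, Z in enumerate(Zs):
            if sig[k] > 0:
                V += sig[k] * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        ViX = Vi @ ones
        P = Vi - ViX @ np.linalg.solve(ones.T @ ViX, ViX.T)
        Py = P @ y
        new = sig.copy()
        for k, Z in enumerate(Zs):
            if sig[k] <= 0:
                continue
            u = sig[k] * (Z.T @ Py)
            tr = np.trace(Z.T @ P @ Z)
            new[k] = (u @ u + sig[k] * qs[k] - sig[k] ** 2 * tr) / qs[k]
        e_hat = sig[3] * Py
        new[3] = (e_hat @ e_hat + sig[3] * n - sig[3] ** 2 * np.trace(P)) / n
        new = np.maximum(new, 0.0)
        if np.max(np.abs(new - sig)) < tol * (1 + np.max(sig)):
            sig = new
            break
        sig = new
    return VarianceComponents(sig[0], sig[1], sig[2], sig[3],
                              e=len(cond.categories),
                              gxe_confounded=not has_reps)


def estimate_variance_components(values, grouping=None) -> VarianceComponents:
    """Partition trait variance into G, E, GxE and residual components.

    ``values``: tidy frame (sample_id, condition, value) or a wide frame
    (samples x conditions).  ``grouping`` optionally maps sample_id to a
    genotype id (clonal replicates); by default every sample is its own
    genotype.
    """
    tidy = _tidy_values(values, grouping)
    a = tidy["genotype"].nunique()
    b = tidy["condition"].nunique()
    if b < 2:
        raise ValueError("need at least 2 conditions")
    if a < 2:
        raise ValueError("need at least 2 genotypes")
    if len(tidy) <= a:
        raise ValueError("fully confounded design: one observation per genotype")
    counts = tidy.groupby(["genotype", "condition"]).size()
    balanced = (len(counts) == a * b) and counts.nunique() == 1
    if balanced:
        return _anova_components(tidy)
    return _em_reml(tidy)


# --------------------------------------------------------------------------
# genetic effects and correlations


def genetic_effects(genotypes: GenotypeMatrix, panel: _TidyPanel,
                    conditions=None) -> dict[tuple[str, int], pd.Series]:
    """Per-individual genetic values from a marker-ridge (rrBLUP) mixed model.

    Fits the GBLUP model separately for each (variable, condition) of the
    panel and returns the training-sample BLUPs keyed by (variable,
    condition).  Works for trait panels and ChlF panels alike.
    """
    from .predictors import fit_gblup

    conds = list(conditions) if conditions is not None else panel.conditions
    wide = panel.wide(conds)
    wide = wide.loc[[s for s in genotypes.sample_ids if s in wide.index]]
    idx = [list(genotypes.sample_ids).index(s) for s in wide.index]
    X = genotypes.codes[idx]
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before computing genetic effects")
    out: dict[tuple[str, int], pd.Series] = {}
    for var in panel.variables:
        for c in conds:
            col = f"{var}_{c}"
            if col not in wide.columns:
                continue
            fit = fit_gblup(X, wide[col].to_numpy(float))
            out[(var, c)] = pd.Series(fit.u, index=wide.index)
    return out


def genetic_correlation_matrix(ge_rows: dict[tuple[str, int], pd.Series],
                               ge_cols: dict[tuple[str, int], pd.Series]
                               ) -> pd.DataFrame:
    """Pearson correlations between genetic-effect vectors.

    With 3 traits and 18 ChlF parameters over 3 conditions this is the
    9 x 54 genetic-correlation matrix.  Zero-variance vectors yield NaN
    (undefined) entries.
    """
    def label(key):
        return f"{key[0]}_{key[1]}"

    rows = list(ge_rows)
    cols = list(ge_cols)
    mat = pd.DataFrame(index=[label(k) for k in rows],
                       columns=[label(k) for k in cols], dtype=float)
    for rk in rows:
        for ck in cols:
            a, b = ge_rows[rk].align(ge_cols[ck], join="inner")
            if a.std() == 0 or b.std() == 0:
                val = np.nan
            else:
                val = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
            mat.loc[label(rk), label(ck)] = val
    return mat


def phenotypic_correlation_matrix(panel_rows: _TidyPanel, panel_cols: _TidyPanel,
                                  conditions=None) -> pd.DataFrame:
    """Pearson correlations between raw phenotype vectors (variable x
    condition), the phenotypic counterpart of the genetic-effect
    correlation matrix."""
    conds_r = list(conditions) if conditions is not None else panel_rows.conditions
    conds_c = list(conditions) if conditions is not None else panel_cols.conditions
    wr = panel_rows.wide(conds_r)
    wc = panel_cols.wide(conds_c)
    common = [s for s in wr.index if s in set(wc.index)]
    wr, wc = wr.loc[common], wc.loc[common]
    mat = pd.DataFrame(index=wr.columns, columns=wc.columns, dtype=float)
    for a in wr.columns:
        for b in wc.columns:
            x, y = wr[a].to_numpy(float), wc[b].to_numpy(float)
            mat.loc[a, b] = (np.nan if x.std() == 0 or y.std() == 0
                             else float(np.corrcoef(x, y)[0, 1]))
    return mat


def hotelling_t2(perf_a: np.ndarray, perf_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Hotelling T-squared test with the exact F transformation.

    Rows are observations (e.g. prediction methods), columns the performance
    variables (e.g. per-trait mean predictabilities).  Returns (T2, p-value).
    """
    A = np.atleast_2d(np.asarray(perf_a, float))
    B = np.atleast_2d(np.asarray(perf_b, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("performance matrices must have the same number of columns")
    n1, p = A.shape
    n2 = B.shape[0]
    if p >= n1 + n2 - 1:
        raise ValueError("dimension too large for the pooled covariance "
                         f"(p={p}, n1+n2-2={n1 + n2 - 2})")
    d = A.mean(axis=0) - B.mean(axis=0)
    S = (((n1 - 1) * np.cov(A, rowvar=False, ddof=1).reshape(p, p)
          + (n2 - 1) * np.cov(B, rowvar=False, ddof=1).reshape(p, p))
         / (n1 + n2 - 2))
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d))
    f_stat = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
    pval = float(stats.f.sf(f_stat, p, n1 + n2 - p - 1))
    return t2, pval


def heritability_table(genotypes: GenotypeMatrix, panel: _TidyPanel,
                       grouping=None, conventional: bool = False) -> pd.DataFrame:
    """H2 per panel variable from the G/E/GxE variance partition."""
    rows = []
    for var in panel.variables:
        sub = panel.data[panel.data["variable"] == var]
        vc = estimate_variance_components(
            sub[["sample_id", "condition", "value"]], grouping)
        rows.append({"variable": var, "var_G": vc.var_G, "var_E": vc.var_E,
                     "var_GxE": vc.var_GxE, "var_eps": vc.var_eps, "e": vc.e,
                     "H2": broad_sense_h2(vc, conventional=conventional)})
    return pd.DataFrame(rows).set_index("variable")
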