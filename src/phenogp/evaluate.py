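"""Cross-validation machinery, predictability scoring, the four evaluation
settings, selection-ability analysis and report generation.

Predictability is the Pearson correlation between predicted and observed
trait values in the validation set; it is undefined (NA) when either vector
has zero standard deviation (e.g. an all-zero-coefficient LASSO fit).
Aggregation order for the cross-validation settings: average predictability
over traits within a fold, then over folds, then over repetitions; NA
repetitions are excluded from the mean and counted.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import predictors
from .preprocess import SettingBlock

#: methods the study applies to phenomic (ChlF) predictors — GBLUP is
#: genomic-relationship based and is used with SNP predictors only
PP_METHODS = tuple(m for m in predictors.METHOD_IDS if m != "GBLUP")

#: desk-scale evaluation profile for end-to-end runs on one CPU: shortened
#: Gibbs chains, compact hyperparameter grids and relaxed coordinate-descent
#: tolerances (full-scale chain defaults remain on the fit functions)
DESK_PROFILE = {
    "chain_length": 400, "burn_in": 100,
    "mbayesb_chain_length": 200, "mbayesb_burn_in": 50,
    "grid_sizes": {"n_lam": 6, "n_mix": 2, "l21_n": 2},
    "tol": 1e-3, "max_iter": 3000,
    "l21_max_iter": 40, "l21_inner_steps": 60,
}


@dataclasses.dataclass
class CVScheme:
    """K-fold scheme with repetitions; nested=True tunes hyperparameters in
    an inner 3-fold loop on the outer-training data."""

    K: int = 3
    repetitions: int = 20
    nested: bool = True
    seed: int = 0
    inner_K: int = 3

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def kfold_partition(sample_ids: Sequence, scheme: CVScheme,
                    repetition: int) -> list[np.ndarray]:
    """Disjoint folds covering all ids, sizes differing by at most one;
    deterministic given (scheme.seed, repetition)."""
    ids = np.asarray(sample_ids, dtype=object)
    n = len(ids)
    if n < scheme.K:
        raise ValueError(f"cannot split {n} samples into {scheme.K} folds")
    rng = np.random.default_rng([scheme.seed, repetition])
    perm = rng.permutation(n)
    return [ids[idx] for idx in np.array_split(perm, scheme.K)]


def predictability(observed, predicted) -> float:
    """Pearson r between observed and predicted; NaN when either side has
    zero standard deviation (the NA convention)."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 3:
        raise ValueError("need at least 3 paired values")
    if obs.std() == 0 or pred.std() == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


@dataclasses.dataclass
class EvaluationRecord:
    """Per-method, per-setting predictability with repetition-level detail.

    ``detail`` has one row per (repetition, fold, trait) score.  The summary
    ``per_repetition`` averages traits within a fold, then folds; ``mean``
    and ``se`` are over the repetition values (NA repetitions excluded).
    """

    setting: str
    family: str
    predictor_source: str
    method: str
    detail: pd.DataFrame
    test_family: str | None = None
    train_condition: int | None = None
    test_condition: int | None = None

    @property
    def per_repetition(self) -> pd.Series:
        fold_means = (self.detail.groupby(["repetition", "fold"])["r"]
                      .mean())  # trait average within fold (NaN skipped)
        return fold_means.groupby("repetition").mean()

    @property
    def mean(self) -> float:
        vals = self.per_repetition.dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def se(self) -> float:
        vals = self.per_repetition.dropna()
        if len(vals) < 2:
            return float("nan")
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))

    @property
    def n_na(self) -> int:
        return int(self.detail["r"].isna().sum())

    @property
    def na_flag(self) -> bool:
        return bool(self.detail["r"].isna().all())

    def per_trait_mean(self) -> pd.Series:
        return self.detail.groupby("trait")["r"].mean()


def _assert_disjoint(train_ids: Iterable, test_ids: Iterable) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(f"train/test sample leak: {sorted(overlap)[:5]}")


def _score_columns(Y_obs: pd.DataFrame, pred: np.ndarray) -> list[float]:
    pred = np.atleast_2d(np.asarray(pred, float))
    if pred.shape[0] == 1 and Y_obs.shape[0] != 1:
        pred = pred.T
    return [predictability(Y_obs.iloc[:, k].to_numpy(), pred[:, k])
            for k in range(Y_obs.shape[1])]


def _check_method_source(method: str, source: str) -> None:
    if method not in predictors.METHOD_IDS:
        raise ValueError(f"unknown method {method!r}")
    if source == "chlf" and method not in PP_METHODS:
        raise ValueError(f"{method} is not applicable to ChlF predictors "
                         "(genomic-relationship model)")


def _select_hyper(method: str, X: pd.DataFrame, Y: pd.DataFrame,
                  scheme: CVScheme, repetition: int,
                  options: dict | None) -> dict:
    """Inner-loop hyperparameter selection by mean validation predictability."""
    options = options or {}
    grid = predictors.default_grid(method, X, Y,
                                   **options.get("grid_sizes", {}))
    if len(grid) <= 1:
        return grid[0] if grid else {}
    inner = CVScheme(K=scheme.inner_K, repetitions=1, seed=scheme.seed + 7919)
    folds = kfold_partition(X.index.to_numpy(object), inner, repetition)
    score = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for f in folds:
        val_ids = list(f)
        train_ids = [s for s in X.index if s not in set(val_ids)]
        fits = predictors.fit_path(method, X.loc[train_ids], Y.loc[train_ids],
                                   grid, options)
        for gi, fit in enumerate(fits):
            pred = predictors.predict(fit, X.loc[val_ids])
            rs = _score_columns(Y.loc[val_ids], pred)
            m = np.nanmean(rs) if not np.all(np.isnan(rs)) else np.nan
            if not np.isnan(m):
                score[gi] += m
                counts[gi] += 1
    with np.errstate(invalid="ignore"):
        mean_score = np.where(counts > 0, score / np.maximum(counts, 1), -np.inf)
    return grid[int(np.argmax(mean_score))]


def nested_cv_evaluate(block: SettingBlock, method: str, scheme: CVScheme,
                       options: dict | None = None) -> EvaluationRecord:
    """Repeated (nested) K-fold evaluation of one method on a CV block.

    Outer loop over K test folds; for tunable methods an inner
    ``scheme.inner_K``-fold loop on the outer-training data selects
    hyperparameters by mean validation predictability; the model is refitted
    on the outer-training data and scored on the test fold.
    """
    if not block.is_cv:
        raise ValueError("nested_cv_evaluate expects a cross-validation block")
    _check_method_source(method, block.predictor_source)
    options = options or {}
    X, Y = block.X_train, block.Y_train
    rows = []
    for rep in range(scheme.repetitions):
        folds = kfold_partition(X.index.to_numpy(object), scheme, rep)
        for fi, fold in enumerate(folds):
            test_ids = list(fold)
            train_ids = [s for s in X.index if s not in set(test_ids)]
            _assert_disjoint(train_ids, test_ids)
            Xtr, Ytr = X.loc[train_ids], Y.loc[train_ids]
            if scheme.nested:
                hyper = _select_hyper(method, Xtr, Ytr, scheme, rep, options)
            else:
                grid = predictors.default_grid(method, Xtr, Ytr,
                                               **options.get("grid_sizes", {}))
                hyper = grid[len(grid) // 2] if grid else {}
            fit = predictors.fit_method(method, Xtr, Ytr, hyper, options)
            pred = predictors.predict(fit, X.loc[test_ids])
            rs = _score_columns(Y.loc[test_ids], pred)
            for trait, r in zip(Y.columns, rs):
                rows.append({"repetition": rep, "fold": fi,
                             "trait": str(trait), "r": r})
    detail = pd.DataFrame(rows)
    return EvaluationRecord(block.setting, block.family, block.predictor_source,
                            method, detail, test_family=block.test_family)


def _fit_predict_block(block: SettingBlock, method: str, scheme: CVScheme,
                       options: dict | None) -> EvaluationRecord:
    """Single train/test evaluation (condition-ahead and cross-family)."""
    _check_method_source(method, block.predictor_source)
    _assert_disjoint(block.X_train.index, block.X_test.index)
    hyper = _select_hyper(method, block.X_train, block.Y_train, scheme, 0,
                          options)
    fit = predictors.fit_method(method, block.X_train, block.Y_train, hyper,
                                options)
    pred = predictors.predict(fit, block.X_test)
    rs = _score_columns(block.Y_test, pred)
    rows = [{"repetition": 0, "fold": 0, "trait": str(tr), "r": r}
            for tr, r in zip(block.Y_test.columns, rs)]
    return EvaluationRecord(block.setting, block.family, block.predictor_source,
                            method, pd.DataFrame(rows),
                            test_family=block.test_family,
                            train_condition=block.train_condition,
                            test_condition=block.test_condition)


def condition_ahead_evaluate(blocks: Sequence[SettingBlock],
                             methods: Sequence[str], scheme: CVScheme,
                             options: dict | None = None) -> list[EvaluationRecord]:
    """Train on one treatment condition, predict the held-out lines in the
    next; hyperparameters are tuned by inner CV on the training condition
    only (no test leakage)."""
    records = []
    for block in blocks:
        if block.setting != "S3":
            raise ValueError("condition_ahead_evaluate expects S3 blocks")
        if len(block.X_test) < 20:
            raise ValueError("condition-ahead evaluation needs 20 held-out samples")
        for method in methods:
            records.append(_fit_predict_block(block, method, scheme, options))
    return records


def cross_family_evaluate(blocks: Sequence[SettingBlock],
                          methods: Sequence[str], scheme: CVScheme,
                          options: dict | None = None) -> list[EvaluationRecord]:
    """Train on one family, score per trait x condition on the other."""
    records = []
    for block in blocks:
        if block.setting != "S4":
            raise ValueError("cross_family_evaluate expects S4 blocks")
        for method in methods:
            records.append(_fit_predict_block(block, method, scheme, options))
    return records


@dataclasses.dataclass
class SelectionAbility:
    method: str
    trait: str
    direction: str
    n_selected: int
    proportion: float  # percent correctly identified

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 100.0:
            raise ValueError("proportion must lie in [0, 100]")


def selection_ability(observed, predicted, n_selected: int = 20,
                      direction: str = "best", method: str = "",
                      trait: str = "") -> SelectionAbility:
    """Proportion of the truly best (or worst) n lines that the model ranks
    within its predicted best (or worst) n.  Ties are broken by stable
    input order."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if direction not in ("best", "worst"):
        raise ValueError("direction must be 'best' or 'worst'")
    if len(obs) != len(pred):
        raise ValueError("length mismatch")
    if n_selected > len(obs):
        raise ValueError("n_selected exceeds the number of lines")
    sign = -1.0 if direction == "best" else 1.0
    top_obs = set(np.argsort(sign * obs, kind="stable")[:n_selected])
    top_pred = set(np.argsort(sign * pred, kind="stable")[:n_selected])
    prop = 100.0 * len(top_obs & top_pred) / n_selected
    return SelectionAbility(method, trait, direction, n_selected, prop)


# --------------------------------------------------------------------------
# orchestration


def run_setting(setting: str, blocks: Sequence[SettingBlock],
                methods: Sequence[str], scheme: CVScheme,
                options: dict | None = None) -> list[EvaluationRecord]:
    """Evaluate all applicable methods on the blocks of one setting.

    GBLUP is silently skipped for ChlF predictors, mirroring its
    genomic-relationship formulation; multi-trait-only methods are skipped
    for single-column responses.
    """
    records: list[EvaluationRecord] = []
    for block in blocks:
        usable = [m for m in methods
                  if not (block.predictor_source == "chlf" and m == "GBLUP")]
        usable = [m for m in usable
                  if not (m == "L21-joint" and block.Y_train.shape[1] < 2)]
        if setting in ("S1", "S2", "S2-augmented"):
            for m in usable:
                records.append(nested_cv_evaluate(block, m, scheme, options))
        elif setting == "S3":
            records.extend(condition_ahead_evaluate([block], usable, scheme,
                                                    options))
        elif setting == "S4":
            records.extend(cross_family_evaluate([block], usable, scheme,
                                                 options))
        else:
            raise ValueError(f"unknown setting {setting!r}")
    return records


def records_frame(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({"setting": r.setting, "family": r.family,
                     "source": r.predictor_source, "method": r.method,
                     "test_family": r.test_family,
                     "train_condition": r.train_condition,
                     "test_condition": r.test_condition,
                     "mean": r.mean, "se": r.se, "n_na": r.n_na})
    return pd.DataFrame(rows)


def per_trait_table(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Methods x traits table of mean predictability (one table per group of
    records that share setting/family/source/conditions)."""
    rows = []
    for r in records:
        means = r.per_trait_mean()
        for trait, val in means.items():
            rows.append({"setting": r.setting, "family": r.family,
                         "source": r.predictor_source,
                         "test_family": r.test_family,
                         "train_condition": r.train_condition,
                         "test_condition": r.test_condition,
                         "method": r.method, "trait": trait, "r": val})
    return pd.DataFrame(rows)


def performance_matrix(records: Sequence[EvaluationRecord],
                       family: str) -> pd.DataFrame:
    """Methods x traits mean-predictability matrix for one family (input to
    the Hotelling T-squared family comparison)."""
    table = per_trait_table([r for r in records if r.family == family])
    return table.pivot_table(index="method", columns="trait", values="r")


def run_study(families: dict, methods: Sequence[str], scheme: CVScheme,
              options: dict | None = None,
              settings: Sequence[str] = ("S1", "S2", "S2-augmented", "S3", "S4"),
              sources: Sequence[str] = ("snp", "chlf")) -> list[EvaluationRecord]:
    """Evaluate all settings x predictor sources on QC'd family data.

    The augmented variant of the AFS setting widens the ChlF predictor block
    and is therefore run for phenomic predictors only (its SNP block would
    duplicate the plain setting).  S4 needs two families and is skipped
    otherwise.
    """
    from .preprocess import assemble_setting

    records: list[EvaluationRecord] = []
    for setting in settings:
        for source in sources:
            if setting == "S2-augmented" and source != "chlf":
                continue
            if setting == "S4" and len(families) != 2:
                continue
            blocks = assemble_setting(setting, families, source)
            records.extend(run_setting(setting, blocks, methods, scheme,
                                       options))
    return records


def selection_ability_records(families: dict, methods: Sequence[str],
                              scheme: CVScheme, options: dict | None = None,
                              n_selected: int = 20) -> list[SelectionAbility]:
    """Best- and worst-line selection ability per method and trait.

    Every line receives an out-of-fold prediction from one K-fold pass
    (fitted on the other folds, hyperparameters tuned inside the training
    folds); lines are then ranked by observed and by predicted value and the
    overlap of the top (bottom) ``n_selected`` sets is scored.
    """
    from .preprocess import assemble_setting

    out: list[SelectionAbility] = []
    for source in ("snp", "chlf"):
        blocks = assemble_setting("S1", families, source)
        for block in blocks:
            X, Y = block.X_train, block.Y_train
            folds = kfold_partition(X.index.to_numpy(object), scheme, 0)
            usable = [m for m in methods
                      if not (source == "chlf" and m == "GBLUP")]
            for method in usable:
                pred = pd.DataFrame(index=X.index, columns=Y.columns,
                                    dtype=float)
                for fold in folds:
                    test_ids = list(fold)
                    train_ids = [i for i in X.index if i not in set(test_ids)]
                    hyper = _select_hyper(method, X.loc[train_ids],
                                          Y.loc[train_ids], scheme, 0, options)
                    fit = predictors.fit_method(method, X.loc[train_ids],
                                                Y.loc[train_ids], hyper,
                                                options)
                    p_fold = np.atleast_2d(
                        predictors.predict(fit, X.loc[test_ids]))
                    if p_fold.shape[0] == 1 and len(test_ids) != 1:
                        p_fold = p_fold.T
                    pred.loc[test_ids, :] = p_fold
                for k, trait in enumerate(Y.columns):
                    obs = Y.iloc[:, k].to_numpy()
                    ns = min(n_selected, len(obs) // 2)
                    for direction in ("best", "worst"):
                        sa = selection_ability(obs, pred.iloc[:, k].to_numpy(),
                                               ns, direction, method=method,
                                               trait=f"{block.family}:{trait}")
                        out.append(sa)
    return out


def make_report(records: Sequence[EvaluationRecord], outdir: str | Path,
                selection: Sequence[SelectionAbility] | None = None,
                heritability: pd.DataFrame | None = None,
                correlations: pd.DataFrame | None = None,
                metadata: dict | None = None) -> dict[str, Path]:
    """Write CSV tables per setting, bar-plot data (means + standard errors),
    optional selection/heritability/correlation tables and run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if records:
        summary = records_frame(records)
        path = outdir / "summary.csv"
        summary.to_csv(path, index=False)
        written["summary"] = path

        traits = per_trait_table(records)
        for (setting, source), grp in traits.groupby(["setting", "source"]):
            idx_cols = ["family"] + [c for c in ("test_family", "train_condition",
                                                 "test_condition")
                                     if grp[c].notna().any()]
            tab = grp.pivot_table(index=idx_cols + ["method"], columns="trait",
                                  values="r")
            path = outdir / f"{setting}_{source}_by_trait.csv"
            tab.to_csv(path)
            written[f"{setting}_{source}"] = path

        bars = summary[["setting", "family", "source", "method", "mean", "se"]]
        path = outdir / "barplot_data.csv"
        bars.to_csv(path, index=False)
        written["barplot_data"] = path

    if selection:
        sel = pd.DataFrame([dataclasses.asdict(s) for s in selection])
        path = outdir / "selection_ability.csv"
        sel.to_csv(path, index=False)
        written["selection"] = path

    if heritability is not None:
        path = outdir / "heritability.csv"
        heritability.to_csv(path)
        written["heritability"] = path

    if correlations is not None:
        path = outdir / "genetic_correlations.csv"
        correlations.to_csv(path)
        written["correlations"] = path

    meta = {"n_records": len(records), **(metadata or {})}
    path = outdir / "metadata.json"
    path.write_text(json.dumps(meta, indent=2, default=str))
    written["metadata"] = path
    return written
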