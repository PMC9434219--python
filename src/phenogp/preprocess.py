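"""Genotype QC, mean imputation, sample matching, and assembly of the
predictor/response blocks for the four evaluation settings.

Filtering rules mirror standard SNP-array practice: markers are dropped when
the minor allele frequency falls below 5% or the call rate below 95%
(strict "<" in both cases, so a marker at exactly the MAF threshold is
kept); samples are dropped when more than 10% of their genotypes are
missing (strict ">") or when they have no match in the phenomic/trait data.
Missing calls that survive filtering are replaced by the marker mean.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .panels import GenotypeMatrix, PhenomicPanel, TraitPanel

SETTINGS = ("S1", "S2", "S2-augmented", "S3", "S4")


@dataclasses.dataclass
class QCReport:
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_markers: dict = dataclasses.field(default_factory=dict)  # id -> reason
    removed_samples: dict = dataclasses.field(default_factory=dict)
    n_imputed: int = 0

    def validate(self) -> None:
        if self.n_markers_in - len(self.removed_markers) != self.n_markers_out:
            raise AssertionError("marker bookkeeping does not close")
        if self.n_samples_in - len(self.removed_samples) != self.n_samples_out:
            raise AssertionError("sample bookkeeping does not close")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def filter_markers(g: GenotypeMatrix, maf_min: float = 0.05,
                   callrate_min: float = 0.95) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with MAF < maf_min or call rate < callrate_min.

    MAF is the folded allele frequency mean(code)/2 over non-missing calls.
    A marker with no observed calls falls under the call-rate rule.
    """
    codes = g.codes
    n = g.n_samples
    with np.errstate(invalid="ignore"):
        call_rate = 1.0 - np.isnan(codes).sum(axis=0) / n
        mean_code = np.nanmean(np.where(np.isnan(codes), np.nan, codes), axis=0)
    af = mean_code / 2.0
    maf = np.minimum(af, 1.0 - af)
    report = QCReport(n_markers_in=g.n_markers, n_samples_in=n, n_samples_out=n)
    keep = np.ones(g.n_markers, dtype=bool)
    for j, mid in enumerate(g.marker_ids):
        if call_rate[j] < callrate_min:
            report.removed_markers[mid] = "call-rate"
            keep[j] = False
        elif np.isnan(maf[j]) or maf[j] < maf_min:
            report.removed_markers[mid] = "MAF"
            keep[j] = False
    out = g.subset(marker_idx=keep)
    report.n_markers_out = out.n_markers
    report.validate()
    return out, report


def filter_samples(g: GenotypeMatrix, phen: PhenomicPanel, traits: TraitPanel,
                   max_missing: float = 0.10) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples with missing-genotype fraction > max_missing (strict)
    or without a match in both the phenomic and trait panels.  Surviving
    sample order is preserved."""
    miss_frac = np.isnan(g.codes).mean(axis=1)
    phen_ids = set(phen.sample_ids)
    trait_ids = set(traits.sample_ids)
    report = QCReport(n_markers_in=g.n_markers, n_markers_out=g.n_markers,
                      n_samples_in=g.n_samples)
    keep = np.ones(g.n_samples, dtype=bool)
    for i, sid in enumerate(g.sample_ids):
        if sid not in phen_ids or sid not in trait_ids:
            report.removed_samples[sid] = "unmatched"
            keep[i] = False
        elif miss_frac[i] > max_missing:
            report.removed_samples[sid] = "missingness"
            keep[i] = False
    if not keep.any():
        raise ValueError("no samples survive matching/missingness filters: "
                         "check id congruence between genotype and panels")
    out = g.subset(sample_idx=keep)
    report.n_samples_out = out.n_samples
    report.validate()
    return out, report


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing entry by its marker's mean over observed calls
    (real-valued, not rounded).  Markers with no observed calls must have
    been removed upstream."""
    codes = g.codes.copy()
    all_missing = np.isnan(codes).all(axis=0)
    if all_missing.any():
        bad = list(np.asarray(g.marker_ids)[all_missing][:5])
        raise ValueError(f"markers with no observed calls cannot be imputed: {bad}")
    col_means = np.nanmean(codes, axis=0)
    nan_r, nan_c = np.where(np.isnan(codes))
    codes[nan_r, nan_c] = col_means[nan_c]
    return GenotypeMatrix(g.sample_ids, g.marker_ids, codes)


def qc_pipeline(g: GenotypeMatrix, phen: PhenomicPanel, traits: TraitPanel,
                maf_min: float = 0.05, callrate_min: float = 0.95,
                max_missing: float = 0.10):
    """Full QC: marker filters, sample filters, marker re-check, imputation.

    Returns (genotypes, phen, traits, QCReport) with panels restricted to the
    surviving samples.
    """
    g1, rep_m = filter_markers(g, maf_min, callrate_min)
    g2, rep_s = filter_samples(g1, phen, traits, max_missing)
    g3, rep_m2 = filter_markers(g2, maf_min, callrate_min)
    n_missing = int(np.isnan(g3.codes).sum())
    g4 = impute_mean(g3)
    report = QCReport(
        n_markers_in=g.n_markers, n_markers_out=g4.n_markers,
        n_samples_in=g.n_samples, n_samples_out=g4.n_samples,
        removed_markers={**rep_m.removed_markers, **rep_m2.removed_markers},
        removed_samples=rep_s.removed_samples,
        n_imputed=n_missing)
    report.validate()
    keep = list(g4.sample_ids)
    return g4, phen.restrict(keep), traits.restrict(keep), report


class FamilyData(NamedTuple):
    """QC'd, imputed inputs of one family."""

    genotypes: GenotypeMatrix
    phenomics: PhenomicPanel
    traits: TraitPanel


@dataclasses.dataclass
class SettingBlock:
    """Train/test predictor and response blocks for one evaluation unit."""

    setting: str
    predictor_source: str               # "snp" | "chlf"
    family: str
    X_train: pd.DataFrame
    Y_train: pd.DataFrame
    X_test: pd.DataFrame | None = None  # None for cross-validation settings
    Y_test: pd.DataFrame | None = None
    train_condition: int | None = None
    test_condition: int | None = None
    test_family: str | None = None

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.X_test is not None:
            if list(self.X_train.columns) != list(self.X_test.columns):
                raise ValueError("train/test predictor columns differ")
            overlap = set(self.X_train.index) & set(self.X_test.index)
            if overlap:
                raise ValueError(f"samples appear in both train and test: "
                                 f"{sorted(overlap)[:5]}")

    @property
    def is_cv(self) -> bool:
        return self.X_test is None

    def write_csv(self, outdir: str | Path, tag: str = "") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{self.setting}_{self.predictor_source}_{self.family}{tag}"
        self.X_train.to_csv(outdir / f"{stem}_train_predictors.csv")
        self.Y_train.to_csv(outdir / f"{stem}_train_responses.csv")
        if self.X_test is not None:
            self.X_test.to_csv(outdir / f"{stem}_test_predictors.csv")
            self.Y_test.to_csv(outdir / f"{stem}_test_responses.csv")


def _snp_frame(fd: FamilyData) -> pd.DataFrame:
    return fd.genotypes.to_frame()


def _aligned(fd: FamilyData, X: pd.DataFrame, Y: pd.DataFrame):
    common = [s for s in fd.genotypes.sample_ids if s in X.index and s in Y.index]
    return X.loc[common], Y.loc[common]


def assemble_setting(setting: str, families: dict[str, FamilyData],
                     predictor_source: str, target_condition: int | None = None,
                     holdout: int = 20,
                     permute_seed: int | None = None) -> list[SettingBlock]:
    """Build SettingBlocks for one evaluation setting.

    S1: per family, responses = 3 traits x all conditions, predictors = full
    SNP matrix or all-condition ChlF block.  S2: responses at one condition
    (default: the shade/AFS treatment, condition 3); "S2-augmented" widens
    the ChlF predictors to all conditions.  S3: per family, the ordered
    condition pairs (2,3), (3,4), (2,4) with the first ``holdout`` samples
    (input order, or a seeded permutation) excluded from training and used
    as the test set.  S4: requires two families; trains on one and tests on
    the other over the shared predictor columns, both directions.
    """
    if predictor_source not in ("snp", "chlf"):
        raise ValueError("predictor_source must be 'snp' or 'chlf'")
    blocks: list[SettingBlock] = []

    if setting in ("S1", "S2", "S2-augmented"):
        for fid, fd in families.items():
            conds = fd.traits.conditions
            if setting == "S1":
                Y = fd.traits.wide(conds)
                X = _snp_frame(fd) if predictor_source == "snp" else fd.phenomics.wide(conds)
            else:
                tc = target_condition if target_condition is not None else conds[1]
                Y = fd.traits.wide([tc])
                if predictor_source == "snp":
                    X = _snp_frame(fd)
                else:
                    X = (fd.phenomics.wide(conds) if setting == "S2-augmented"
                         else fd.phenomics.wide([tc]))
            X, Y = _aligned(fd, X, Y)
            blocks.append(SettingBlock(setting, predictor_source, fid, X, Y))
        return blocks

    if setting == "S3":
        for fid, fd in families.items():
            conds = fd.traits.conditions
            pairs = [(conds[0], conds[1]), (conds[1], conds[2]),
                     (conds[0], conds[2])] if len(conds) >= 3 else [tuple(conds)]
            samples = list(fd.genotypes.sample_ids)
            if len(samples) <= holdout:
                raise ValueError(f"S3 needs more than {holdout} samples, "
                                 f"family {fid} has {len(samples)}")
            order = list(samples)
            if permute_seed is not None:
                order = list(np.random.default_rng(permute_seed).permutation(samples))
            test_ids, train_ids = order[:holdout], order[holdout:]
            for tr_c, te_c in pairs:
                if predictor_source == "snp":
                    Xall = _snp_frame(fd)
                    X_train, X_test = Xall.loc[train_ids], Xall.loc[test_ids]
                else:
                    X_train = fd.phenomics.wide([tr_c], suffix=False).loc[train_ids]
                    X_test = fd.phenomics.wide([te_c], suffix=False).loc[test_ids]
                Y_train = fd.traits.wide([tr_c]).loc[train_ids]
                Y_test = fd.traits.wide([te_c]).loc[test_ids]
                blocks.append(SettingBlock(
                    "S3", predictor_source, fid, X_train, Y_train, X_test, Y_test,
                    train_condition=tr_c, test_condition=te_c))
        return blocks

    if setting == "S4":
        if len(families) != 2:
            raise ValueError("S4 requires exactly two families")
        (fa, da), (fb, db) = families.items()
        for (f_tr, d_tr), (f_te, d_te) in (((fa, da), (fb, db)), ((fb, db), (fa, da))):
            conds = d_tr.traits.conditions
            if predictor_source == "snp":
                shared = [m for m in d_tr.genotypes.marker_ids
                          if m in set(d_te.genotypes.marker_ids)]
                if not shared:
                    raise ValueError("no shared markers between families")
                X_train = _snp_frame(d_tr)[shared]
                X_test = _snp_frame(d_te)[shared]
            else:
                ros_tr = d_tr.phenomics.wide(conds).columns
                ros_te = d_te.phenomics.wide(conds).columns
                if list(ros_tr) != list(ros_te):
                    raise ValueError("ChlF column rosters differ between families")
                X_train = d_tr.phenomics.wide(conds)
                X_test = d_te.phenomics.wide(conds)
            Y_train = d_tr.traits.wide(conds)
            Y_test = d_te.traits.wide(conds)
            X_train, Y_train = X_train.loc[Y_train.index], Y_train
            blocks.append(SettingBlock(
                "S4", predictor_source, f_tr, X_train, Y_train, X_test, Y_test,
                test_family=f_te))
        return blocks

    raise ValueError(f"unknown setting {setting!r}")
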