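"""Synthetic three-way-hybrid study generator with known ground truth.

The generator emulates the structure of a two-family coffee H3W study: a
highly heterozygous F1 parent is crossed to two mostly homozygous landrace
lines, giving two half-sib families that share one parent.  Each offspring
genotype is one random gamete from the shared parent plus one from the line
parent (independent sites, no linkage map).  Traits follow

    y_{i,t,c} = mu_t + g_{i,t} + E_{t,c} + (GxE)_{i,t,c} + eps_{i,t,c}

with genetic values g = (X - Xbar) B from sparse marker effects, and the 18
ChlF endophenotypes are generated as loadings on the (standardized) trait
genetic values plus an independent ChlF-specific genetic part and noise, so
the trait-ChlF genetic correlations are known by construction.

Each realized variance component is rescaled in-sample to its configured
value exactly ("variance-exact" simulation), which makes the downstream
recovery targets sharp.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .panels import CHLF_PARAMS, TRAITS, GenotypeMatrix, PhenomicPanel, TraitPanel


def _as_trait_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n)
    if arr.size != n:
        raise ValueError(f"{name} must be scalar or length {n}")
    return arr


def default_chlf_loading(n_traits: int = 3, n_chlf: int = 18) -> np.ndarray:
    """Default trait x ChlF genetic-loading matrix.

    Mirrors a study regime where each trait is moderately genetically
    correlated with a handful of ChlF parameters (maxima around 0.3-0.4)
    and uncorrelated with the rest.
    """
    maxima = (0.35, 0.38, 0.30)
    load = np.zeros((n_traits, n_chlf))
    for t in range(n_traits):
        base = 3 * t
        load[t, base % n_chlf] = maxima[t % len(maxima)]
        load[t, (base + 1) % n_chlf] = 0.20
        load[t, (base + 2) % n_chlf] = 0.15
    return load


def chlf_dominant_loading(n_traits: int = 3, n_chlf: int = 18) -> np.ndarray:
    """Loading regime where ChlF carries most of the trait-genetic signal."""
    load = np.zeros((n_traits, n_chlf))
    for t in range(n_traits):
        for j in range(4):
            load[t, (4 * t + j) % n_chlf] = 0.45
    return load


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Variances are per trait (scalar broadcasts to all three).  The parental
    heterozygosity defaults follow the study populations: the shared F1
    parent is heterozygous at ~84% of retained sites, the two landrace line
    parents at ~14% and ~12%.
    """

    n_individuals: int = 74
    n_markers: int = 2000
    n_conditions: int = 3
    n_chlf: int = 18
    parent_heterozygosity: tuple[float, float, float] = (0.84, 0.14, 0.12)
    n_qtl: int = 20
    var_G: float | Sequence[float] = 1.0
    var_E: float | Sequence[float] = 1.0
    var_GxE: float | Sequence[float] = 0.6
    var_eps: float | Sequence[float] = 0.6
    chlf_genetic_loading: np.ndarray | None = None
    chlf_h2: float | Sequence[float] | None = None
    trait_means: tuple[float, float, float] = (30.0, 80.0, 10.0)
    missing_rate_markers: float = 0.02
    missing_rate_samples: float = 0.05
    elevated_missing_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(TRAITS)
        self.var_G = _as_trait_vector(self.var_G, t, "var_G")
        self.var_E = _as_trait_vector(self.var_E, t, "var_E")
        self.var_GxE = _as_trait_vector(self.var_GxE, t, "var_GxE")
        self.var_eps = _as_trait_vector(self.var_eps, t, "var_eps")
        for name in ("var_G", "var_E", "var_GxE", "var_eps"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        for h in self.parent_heterozygosity:
            if not 0.0 <= h <= 1.0:
                raise ValueError("heterozygosity fractions must lie in [0, 1]")
        for name in ("missing_rate_markers", "missing_rate_samples",
                     "elevated_missing_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.chlf_genetic_loading is None:
            self.chlf_genetic_loading = default_chlf_loading(len(TRAITS), self.n_chlf)
        self.chlf_genetic_loading = np.asarray(self.chlf_genetic_loading, float)
        if self.chlf_genetic_loading.shape != (len(TRAITS), self.n_chlf):
            raise ValueError("chlf_genetic_loading must be traits x n_chlf")
        if np.any(np.abs(self.chlf_genetic_loading) > 1):
            raise ValueError("chlf_genetic_loading entries must lie in [-1, 1]")
        if np.any(np.sum(self.chlf_genetic_loading ** 2, axis=0) > 1 + 1e-12):
            raise ValueError("per-ChlF squared loadings must sum to <= 1")
        # ChlF genetic share per parameter: parameters genetically tied to the
        # growth traits sit at the top of the observed ChlF heritability range
        # (broad-sense ~0.24), unloaded ones are barely heritable
        if self.chlf_h2 is None:
            loaded = np.any(self.chlf_genetic_loading != 0, axis=0)
            self.chlf_h2 = np.where(loaded, 0.38, 0.10)
        self.chlf_h2 = _as_trait_vector(self.chlf_h2, self.n_chlf, "chlf_h2")
        if np.any(self.chlf_h2 < 0) or np.any(self.chlf_h2 > 1):
            raise ValueError("chlf_h2 must lie in [0, 1]")

    @property
    def conditions(self) -> list[int]:
        # post-acclimation treatments are numbered 2..4 in the study design
        return list(range(2, 2 + self.n_conditions))


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    marker_effects: np.ndarray          # markers x traits
    genetic_main: np.ndarray            # individuals x traits
    genetic_values: np.ndarray          # individuals x traits x conditions
    gxe: np.ndarray                     # individuals x traits x conditions
    condition_effects: np.ndarray       # traits x conditions
    genetic_offset: np.ndarray          # traits; genetic_main = X @ B - offset
    chlf_genetic: np.ndarray            # individuals x n_chlf
    variance_components_true: dict[str, np.ndarray]
    h2_true: np.ndarray                 # per trait

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_effects": self.marker_effects.tolist(),
            "genetic_main": self.genetic_main.tolist(),
            "genetic_values": self.genetic_values.tolist(),
            "gxe": self.gxe.tolist(),
            "condition_effects": self.condition_effects.tolist(),
            "genetic_offset": self.genetic_offset.tolist(),
            "chlf_genetic": self.chlf_genetic.tolist(),
            "variance_components_true": {k: v.tolist() for k, v in
                                         self.variance_components_true.items()},
            "h2_true": self.h2_true.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _draw_parent(rng: np.random.Generator, n_markers: int, het: float) -> np.ndarray:
    """Diploid parental genome as a (2, markers) array of alleles in {0, 1}."""
    het_site = rng.random(n_markers) < het
    hom_alt = rng.random(n_markers) < 0.5
    a = np.where(het_site, 0, np.where(hom_alt, 1, 0))
    b = np.where(het_site, 1, a)
    # randomize which haplotype carries the alt allele at het sites
    flip = rng.random(n_markers) < 0.5
    a2 = np.where(het_site & flip, b, a)
    b2 = np.where(het_site & flip, a, b)
    return np.stack([a2, b2])


def _gametes(rng: np.random.Generator, parent: np.ndarray, n: int) -> np.ndarray:
    """n random gametes (independent sites) from a (2, markers) parent."""
    pick = rng.integers(0, 2, size=(n, parent.shape[1]))
    return np.where(pick == 0, parent[0], parent[1])


def _scale_to_variance(x: np.ndarray, target: float, ddof: int = 1) -> np.ndarray:
    """Center and rescale so the sample variance equals target exactly."""
    x = x - x.mean()
    v = x.var(ddof=ddof)
    if v <= 0 or target == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target / v)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def _draw_marker_effects(rng, n_markers: int, n_traits: int, n_qtl: int) -> np.ndarray:
    """Sparse effect matrix: disjoint QTL sets per trait where possible."""
    B = np.zeros((n_markers, n_traits))
    perm = rng.permutation(n_markers)
    for t in range(n_traits):
        if n_traits * n_qtl <= n_markers:
            qtl = perm[t * n_qtl:(t + 1) * n_qtl]
        else:
            qtl = rng.choice(n_markers, size=n_qtl, replace=False)
        B[qtl, t] = rng.normal(size=n_qtl)
    return B


def _chlf_specific_genetic(rng, X: np.ndarray, n_chlf: int, n_qtl: int) -> np.ndarray:
    """Standardized ChlF-specific genetic components from their own QTL."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    out = np.empty((n, n_chlf))
    for k in range(n_chlf):
        qtl = rng.choice(p, size=min(n_qtl, p), replace=False)
        out[:, k] = _standardize(Xc[:, qtl] @ rng.normal(size=len(qtl)))
    return out


def _build_family(config: SimConfig, rng: np.random.Generator, family_id: str,
                  shared_parent: np.ndarray, line_parent: np.ndarray,
                  marker_effects: np.ndarray, n: int,
                  effect_scale: np.ndarray | None = None):
    """Assemble genotypes, panels and truth for one family.

    When ``effect_scale`` is given (study mode) marker effects are used as-is
    after that scaling; otherwise effects are rescaled so the in-sample
    genetic variance per trait equals config.var_G exactly.
    """
    p = config.n_markers
    t = len(TRAITS)
    conds = config.conditions

    g_shared = _gametes(rng, shared_parent, n)
    g_line = _gametes(rng, line_parent, n)
    X = (g_shared + g_line).astype(float)
    sample_ids = np.array([f"{family_id}_{i + 1:03d}" for i in range(n)], dtype=object)
    marker_ids = np.array([f"M{j + 1:05d}" for j in range(p)], dtype=object)

    # genetic values; scale effects so var(g) hits var_G exactly per trait
    B = marker_effects.copy()
    g_raw = X @ B
    scale = np.ones(t)
    for k in range(t):
        if effect_scale is not None:
            scale[k] = effect_scale[k]
        else:
            sd = (g_raw[:, k] - g_raw[:, k].mean()).std(ddof=1)
            scale[k] = np.sqrt(config.var_G[k]) / sd if sd > 0 else 0.0
    B *= scale
    g_all = X @ B
    offset = g_all.mean(axis=0)
    g = g_all - offset                    # genetic_main = X @ B - offset

    nc = len(conds)
    E = np.zeros((t, nc))
    gxe = np.zeros((n, t, nc))
    eps = np.zeros((n, t, nc))
    Y = np.zeros((n, t, nc))
    for k in range(t):
        E[k] = _scale_to_variance(rng.normal(size=nc), config.var_E[k])
        gxe[:, k, :] = _scale_to_variance(
            rng.normal(size=(n, nc)).ravel(), config.var_GxE[k]).reshape(n, nc)
        eps[:, k, :] = _scale_to_variance(
            rng.normal(size=(n, nc)).ravel(), config.var_eps[k]).reshape(n, nc)
        for c in range(nc):
            Y[:, k, c] = (config.trait_means[k] + g[:, k] + E[k, c]
                          + gxe[:, k, c] + eps[:, k, c])

    # ChlF: loadings on standardized trait genetic values + ChlF-specific
    # genetic part + condition shift + measurement noise
    g_std = np.column_stack([_standardize(g[:, k]) for k in range(t)])
    load = config.chlf_genetic_loading
    resid_load = np.sqrt(np.clip(1.0 - np.sum(load ** 2, axis=0), 0.0, None))
    own = _chlf_specific_genetic(rng, X, config.n_chlf, config.n_qtl)
    gamma = g_std @ load + own * resid_load       # n x n_chlf, unit-ish variance
    shifts = rng.normal(size=(config.n_chlf, nc))
    chlf = np.zeros((n, config.n_chlf, nc))
    sg = np.sqrt(config.chlf_h2)[None, :]
    se = np.sqrt(1.0 - config.chlf_h2)[None, :]
    for c in range(nc):
        chlf[:, :, c] = (shifts[:, c][None, :] + sg * gamma
                         + se * rng.normal(size=(n, config.n_chlf)))

    from . import quantgen  # late import: quantgen does not import syndata

    vc_true = {"var_G": config.var_G.copy(), "var_E": config.var_E.copy(),
               "var_GxE": config.var_GxE.copy(), "var_eps": config.var_eps.copy()}
    h2_true = np.array([
        quantgen.broad_sense_h2(quantgen.VarianceComponents(
            config.var_G[k], config.var_E[k], config.var_GxE[k],
            config.var_eps[k], e=nc)) for k in range(t)])

    genotypes = GenotypeMatrix(sample_ids, marker_ids, X)
    chlf_names = list(CHLF_PARAMS[:config.n_chlf])
    phen = PhenomicPanel.from_wide(
        {(chlf_names[j], conds[c]): chlf[:, j, c]
         for j in range(config.n_chlf) for c in range(nc)}, sample_ids)
    traits = TraitPanel.from_wide(
        {(TRAITS[k], conds[c]): Y[:, k, c] for k in range(t) for c in range(nc)},
        sample_ids)
    truth = SimTruth(
        marker_effects=B,
        genetic_main=g,
        genetic_values=g[:, :, None] + gxe,
        gxe=gxe,
        condition_effects=E,
        genetic_offset=offset,
        chlf_genetic=gamma,
        variance_components_true=vc_true,
        h2_true=h2_true,
    )
    return genotypes, phen, traits, truth


def simulate_family(config: SimConfig, family: int = 0, family_id: str | None = None):
    """Simulate one half-sib family: shared F1 parent x one line parent.

    ``family`` selects which line parent's heterozygosity is used (0 or 1).

    Returns (GenotypeMatrix, PhenomicPanel, TraitPanel, SimTruth);
    bit-reproducible under a fixed config.seed.
    """
    if family not in (0, 1):
        raise ValueError("family must be 0 or 1")
    rng = np.random.default_rng(config.seed)
    shared = _draw_parent(rng, config.n_markers, config.parent_heterozygosity[0])
    lines = [_draw_parent(rng, config.n_markers, config.parent_heterozygosity[1 + i])
             for i in range(2)]
    effects = _draw_marker_effects(rng, config.n_markers, len(TRAITS), config.n_qtl)
    fid = family_id or f"F{family + 1}"
    return _build_family(config, rng, fid, shared, lines[family], effects,
                         config.n_individuals)


def simulate_study(config: SimConfig, sizes: tuple[int, int] = (74, 119),
                   family_ids: tuple[str, str] = ("H1xET47", "H1xG")):
    """Simulate the full two-family study with a shared F1 parent genome.

    Marker effects are shared between families and scaled on the pooled
    population, so the genetic architecture transfers across families (the
    basis of the cross-family evaluation setting).  Returns a dict
    family_id -> (GenotypeMatrix, PhenomicPanel, TraitPanel, SimTruth).
    """
    rng = np.random.default_rng(config.seed)
    shared = _draw_parent(rng, config.n_markers, config.parent_heterozygosity[0])
    lines = [_draw_parent(rng, config.n_markers, config.parent_heterozygosity[1 + i])
             for i in range(2)]
    effects = _draw_marker_effects(rng, config.n_markers, len(TRAITS), config.n_qtl)

    # pooled effect scaling: draw both families' genotypes first
    gametes = [( _gametes(rng, shared, n), _gametes(rng, lines[i], n))
               for i, n in enumerate(sizes)]
    X_pool = np.vstack([(a + b).astype(float) for a, b in gametes])
    g_pool = X_pool @ effects
    scale = np.empty(len(TRAITS))
    for k in range(len(TRAITS)):
        sd = g_pool[:, k].std(ddof=1)
        scale[k] = np.sqrt(config.var_G[k]) / sd if sd > 0 else 0.0

    out = {}
    for i, (fid, n) in enumerate(zip(family_ids, sizes)):
        out[fid] = _build_family(config, rng, fid, shared, lines[i], effects, n,
                                 effect_scale=scale)
    return out


def inject_missingness(genotypes: GenotypeMatrix, config: SimConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Set entries missing at config.missing_rate_markers, plus elevated
    missingness (config.elevated_missing_rate) for a config.missing_rate_samples
    fraction of samples so the sample-missingness filter has work to do."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    codes = genotypes.codes.copy()
    n, p = codes.shape
    mask = rng.random((n, p)) < config.missing_rate_markers
    n_elev = int(round(config.missing_rate_samples * n))
    if n_elev:
        rows = rng.choice(n, size=n_elev, replace=False)
        mask[rows] |= rng.random((n_elev, p)) < config.elevated_missing_rate
    codes[mask] = np.nan
    return GenotypeMatrix(genotypes.sample_ids, genotypes.marker_ids, codes)


def realized_h2(truth: SimTruth, traits: TraitPanel) -> np.ndarray:
    """Heritability implied by the empirical variance components of the panel.

    Decomposes each trait's panel using the known genetic values and GxE
    deviations; the remaining condition means and residuals give var_E and
    var_eps.  Raises on a degenerate (zero total variance) panel.
    """
    wide_by_trait = []
    conds = traits.conditions
    for k, tr in enumerate(TRAITS):
        w = traits.wide()
        cols = [f"{tr}_{c}" for c in conds]
        wide_by_trait.append(w[cols].to_numpy(float))
    h2 = np.empty(len(TRAITS))
    from . import quantgen

    for k in range(len(TRAITS)):
        y = wide_by_trait[k]
        if np.allclose(y.var(), 0) and np.allclose(truth.genetic_main[:, k].var(), 0):
            raise ValueError(f"degenerate simulation: trait {TRAITS[k]} has zero variance")
        g = truth.genetic_main[:, k]
        resid1 = y - g[:, None] - truth.gxe[:, k, :]
        E_hat = resid1.mean(axis=0)
        eps = resid1 - E_hat[None, :]
        vc = quantgen.VarianceComponents(
            var_G=g.var(ddof=1),
            var_E=E_hat.var(ddof=1),
            var_GxE=truth.gxe[:, k, :].ravel().var(ddof=1),
            var_eps=eps.ravel().var(ddof=1),
            e=len(conds))
        h2[k] = quantgen.broad_sense_h2(vc)
    return h2


def write_study(study: dict, outdir: str | Path) -> None:
    """Write a simulated study: genotypes TSV, tidy CSV panels, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fid, (geno, phen, traits, truth) in study.items():
        geno.write_tsv(outdir / f"{fid}_genotypes.tsv")
        phen.write_csv(outdir / f"{fid}_chlf.csv")
        traits.write_csv(outdir / f"{fid}_traits.csv")
        truth.to_json(outdir / f"{fid}_truth.json")
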