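"""Synthetic paired transcriptome + metabolome data with planted structure.

The generator emulates the study conditions of a two-group (pregnant vs
nonpregnant) blood multi-omics design: negative-binomial RNA-Seq counts,
log-normal metabolite peak heights, latent-factor co-expression modules that
can be *gated* to one phenotype group (group-specific network rewiring),
planted differentially expressed features, and planted gene-metabolite pairs
whose slope differs by phenotype (an interaction effect).

Correlated counts use a Gaussian copula: each feature's latent value is a
loading-weighted sum of shared standard-normal module factors plus
independent noise (unit marginal variance), mapped through the
negative-binomial quantile function so marginals stay exactly NB. When a
module is inactive in a sample's group, its factor is replaced by independent
noise of the same variance, so marginals are unchanged while the within-group
correlation disappears — genuine rewiring without differential expression.

Randomness is organised as named streams derived from one seed via
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed counter per
stream, so adding a downstream draw never shifts earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix, ValidationError

__all__ = [
    "ModuleDef",
    "GMPairDef",
    "SimulationSpec",
    "TruthTable",
    "generate",
    "planted_scenario",
    "simulate_interaction_pair",
    "score_against_truth",
]

_STREAMS = {
    "gene_noise": 0,
    "module_factors": 1,
    "gene_baselines": 2,
    "metab_noise": 3,
    "metab_baselines": 4,
    "gm_noise": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class ModuleDef:
    """A latent-factor co-expression module.

    ``groups`` lists the phenotype levels the module is active in; members of
    a module gated to one group are correlated only within that group.
    """

    features: list[str]
    loading: float
    groups: tuple[str, ...]
    layer: str = "gene"


@dataclass
class GMPairDef:
    """A planted gene-metabolite pair with a phenotype-dependent slope.

    The metabolite's log abundance is b1 + b2*g + b4*g*p + noise, with g the
    gene's centered log2 expression and p = 1 in the non-reference group.
    """

    gene: str
    metabolite: str
    b2: float = 0.5
    b4: float = 1.5
    noise_sd: float = 0.5
    b1: float = float(np.log(5e4))


@dataclass
class SimulationSpec:
    n_genes: int = 300
    n_metabolites: int = 30
    n_per_group: int = 6
    nb_dispersion: float = 10.0
    gene_log_mean: float = float(np.log(150.0))
    gene_log_mean_sd: float = 0.4
    metab_log_mean: float = float(np.log(5e4))
    metab_log_mean_sd: float = 0.5
    metab_within_sd: float = 0.08
    module_defs: list[ModuleDef] = field(default_factory=list)
    de_defs: dict[str, float] = field(default_factory=dict)  # feature -> log2 FC (ref/other)
    gm_defs: list[GMPairDef] = field(default_factory=list)
    baseline_override: dict[str, float] = field(default_factory=dict)  # gene -> mean count
    groups: tuple[str, str] = ("NP", "AI-P")
    reference: str = "NP"
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def metab_ids(self) -> list[str]:
        return [f"M{i + 1:03d}" for i in range(self.n_metabolites)]

    def validate(self) -> None:
        known = set(self.gene_ids()) | set(self.metab_ids())
        for mod in self.module_defs:
            bad = [f for f in mod.features if f not in known]
            if bad:
                raise ValidationError(f"module references unknown features: {bad[:5]}")
            if not 0 <= mod.loading < 1:
                raise ValidationError(f"module loading {mod.loading} outside [0, 1)")
            bad_g = [g for g in mod.groups if g not in self.groups]
            if bad_g:
                raise ValidationError(f"module gated to unknown groups: {bad_g}")
        bad = [f for f in self.de_defs if f not in known]
        if bad:
            raise ValidationError(f"DE planted on unknown features: {bad[:5]}")
        bad = [
            f for f, v in self.baseline_override.items()
            if f not in set(self.gene_ids()) or v < 0
        ]
        if bad:
            raise ValidationError(f"invalid baseline overrides: {bad[:5]}")
        for gm in self.gm_defs:
            if gm.gene not in set(self.gene_ids()):
                raise ValidationError(f"unknown gene in gm pair: {gm.gene}")
            if gm.metabolite not in set(self.metab_ids()):
                raise ValidationError(f"unknown metabolite in gm pair: {gm.metabolite}")
        # total module variance per feature must stay below 1
        load2: dict[str, float] = {}
        for mod in self.module_defs:
            for f in mod.features:
                load2[f] = load2.get(f, 0.0) + mod.loading**2
        over = {f: v for f, v in load2.items() if v >= 1}
        if over:
            raise ValidationError(
                f"total squared loading >= 1 for features: {list(over)[:5]}"
            )


@dataclass
class TruthTable:
    """Planted ground truth for scoring every pipeline stage."""

    de_features: dict[str, float]
    rewired_nodes: dict[str, str]  # feature -> the single group its module is gated to
    gm_pairs: list[GMPairDef]

    def gm_pair_keys(self) -> set[tuple[str, str]]:
        return {(p.gene, p.metabolite) for p in self.gm_pairs}


def _latent(
    ids: list[str],
    spec: SimulationSpec,
    layer: str,
    group_of_sample: np.ndarray,
    noise_rng: np.random.Generator,
    factors: dict[int, np.ndarray],
) -> np.ndarray:
    """Unit-variance latent matrix (features x samples) with module structure."""
    n_s = len(group_of_sample)
    idx = {f: i for i, f in enumerate(ids)}
    eps = noise_rng.standard_normal((len(ids), n_s))
    load2 = np.zeros(len(ids))
    signal = np.zeros((len(ids), n_s))
    for mi, mod in enumerate(spec.module_defs):
        if mod.layer != layer:
            continue
        f = factors[mi]  # (n_samples,)
        active = np.isin(group_of_sample, mod.groups)
        # inactive samples: replace the factor with fresh independent noise so
        # the marginal stays standard normal but the correlation vanishes
        for feat in mod.features:
            if feat not in idx:
                continue
            i = idx[feat]
            own = noise_rng.standard_normal(n_s)
            contrib = np.where(active, f, own)
            signal[i] += mod.loading * contrib
            load2[i] += mod.loading**2
    return signal + np.sqrt(1.0 - load2)[:, None] * eps


def generate(
    spec: SimulationSpec,
) -> tuple[FeatureMatrix, FeatureMatrix, TruthTable]:
    """Draw one dataset; bit-reproducible for a fixed spec (incl. seed)."""
    spec.validate()
    ref, other = spec.reference, [g for g in spec.groups if g != spec.reference][0]
    n = spec.n_per_group
    sample_ids = [f"{g.replace('-', '')}_{i + 1:02d}" for g in (ref, other) for i in range(n)]
    phenotype = pd.Series([ref] * n + [other] * n, index=sample_ids)
    group_arr = phenotype.values

    gene_ids, metab_ids = spec.gene_ids(), spec.metab_ids()
    factor_rng = _rng(spec.seed, "module_factors")
    factors = {
        mi: factor_rng.standard_normal(2 * n) for mi in range(len(spec.module_defs))
    }

    # --- genes: NB counts through a Gaussian copula -----------------------
    z = _latent(gene_ids, spec, "gene", group_arr, _rng(spec.seed, "gene_noise"), factors)
    base = np.exp(
        spec.gene_log_mean
        + spec.gene_log_mean_sd * _rng(spec.seed, "gene_baselines").standard_normal(len(gene_ids))
    )
    for feat, mean in spec.baseline_override.items():
        base[gene_ids.index(feat)] = mean
    lfc = np.array([spec.de_defs.get(g, 0.0) for g in gene_ids])
    is_ref = (group_arr == ref).astype(float)[None, :]
    # log2FC convention: positive = higher in the reference (NP) group
    mu = base[:, None] * np.power(2.0, lfc[:, None] * (is_ref - 0.5))
    size = spec.nb_dispersion
    p_nb = size / (size + mu)
    u = stats.norm.cdf(z)
    counts = stats.nbinom.ppf(u, size, p_nb)
    gene_fm = FeatureMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        "gene",
        phenotype,
        spec.reference,
    )

    # --- metabolites: log-normal peak heights -----------------------------
    zm = _latent(
        metab_ids, spec, "metabolite", group_arr, _rng(spec.seed, "metab_noise"), factors
    )
    mbase = (
        spec.metab_log_mean
        + spec.metab_log_mean_sd
        * _rng(spec.seed, "metab_baselines").standard_normal(len(metab_ids))
    )
    mlfc = np.array([spec.de_defs.get(m, 0.0) for m in metab_ids])
    logm = (
        mbase[:, None]
        + np.log(2.0) * mlfc[:, None] * (is_ref - 0.5)
        + spec.metab_within_sd * zm
    )

    # planted gene-metabolite interaction pairs override the module draw
    gm_rng = _rng(spec.seed, "gm_noise")
    glog2 = np.log2(counts + 1.0)
    p_ind = (group_arr != ref).astype(float)
    midx = {m: i for i, m in enumerate(metab_ids)}
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for gm in spec.gm_defs:
        g = glog2[gidx[gm.gene]]
        gc = g - g.mean()
        noise = gm_rng.standard_normal(2 * n) * gm.noise_sd
        logm[midx[gm.metabolite]] = gm.b1 + gm.b2 * gc + gm.b4 * gc * p_ind + noise

    metab_fm = FeatureMatrix(
        pd.DataFrame(np.exp(logm), index=metab_ids, columns=sample_ids),
        "metabolite",
        phenotype,
        spec.reference,
    )

    rewired: dict[str, str] = {}
    for mod in spec.module_defs:
        if len(mod.groups) == 1:
            for f in mod.features:
                rewired[f] = mod.groups[0]
    truth = TruthTable(
        de_features=dict(spec.de_defs),
        rewired_nodes=rewired,
        gm_pairs=list(spec.gm_defs),
    )
    return gene_fm, metab_fm, truth


def planted_scenario(seed: int = 0, n_per_group: int = 50) -> SimulationSpec:
    """The canonical planted-structure study: 300 genes, 30 metabolites.

    Gene layer: ten both-group ("housekeeping") modules of eight genes
    provide the stable network background the differential-connectivity
    z-score needs; one module of six genes is gated to the pregnant (AI-P)
    group and one to NP (planted rewiring). Metabolite layer: two both-group
    modules of five plus a four-metabolite gated module per group. All module
    members carry planted differential expression (|log2FC| = 1) so the
    published DE-anchored network filters keep their edges; eight singleton
    DE genes are added. Three gene-metabolite pairs with interaction slope
    b4 = 1.5 (b2 = 0.5, noise sd 0.5) link genes of the AI-P-gated module to
    otherwise-unstructured metabolites.
    """
    gid = [f"G{i + 1:04d}" for i in range(300)]
    mid = [f"M{i + 1:03d}" for i in range(30)]
    modules: list[ModuleDef] = []
    for b in range(10):
        modules.append(ModuleDef(gid[8 * b : 8 * b + 8], 0.95, ("NP", "AI-P"), "gene"))
    modules.append(ModuleDef(gid[80:86], 0.95, ("AI-P",), "gene"))
    modules.append(ModuleDef(gid[86:92], 0.95, ("NP",), "gene"))
    modules.append(ModuleDef(mid[0:5], 0.95, ("NP", "AI-P"), "metabolite"))
    modules.append(ModuleDef(mid[5:10], 0.95, ("NP", "AI-P"), "metabolite"))
    modules.append(ModuleDef(mid[10:14], 0.95, ("AI-P",), "metabolite"))
    modules.append(ModuleDef(mid[14:18], 0.95, ("NP",), "metabolite"))

    de: dict[str, float] = {}
    for i, g in enumerate(gid[:92] + gid[92:100]):
        de[g] = 1.0 if i % 2 == 0 else -1.0
    for i, m in enumerate(mid[10:18]):
        de[m] = 1.0 if i % 2 == 0 else -1.0

    gm = [
        GMPairDef("G0081", "M019"),
        GMPairDef("G0082", "M020"),
        GMPairDef("G0083", "M021"),
    ]
    # unexpressed and very lowly expressed genes exercise the count filters
    overrides = {g: 0.0 for g in gid[292:296]}
    overrides.update({g: 0.02 for g in gid[296:300]})
    return SimulationSpec(
        n_genes=300,
        n_metabolites=30,
        n_per_group=n_per_group,
        module_defs=modules,
        de_defs=de,
        gm_defs=gm,
        baseline_override=overrides,
        seed=seed,
    )


def simulate_interaction_pair(
    n_per_group: int,
    b: tuple[float, float, float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One (gene, metabolite, phenotype) triplet from the interaction model.

    g ~ N(0, 1); m = b1 + b2*g + b3*p + b4*g*p + N(0, noise_sd^2); phenotype
    array has the reference level 'NP' first.
    """
    n = 2 * n_per_group
    g = rng.standard_normal(n)
    p = np.array([0.0] * n_per_group + [1.0] * n_per_group)
    b1, b2, b3, b4 = b
    m = b1 + b2 * g + b3 * p + b4 * g * p + noise_sd * rng.standard_normal(n)
    phen = np.array(["NP"] * n_per_group + ["AI-P"] * n_per_group)
    return g, m, phen


def _prf(predicted: set, truth: set) -> dict[str, object]:
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}


def score_against_truth(
    truth: TruthTable,
    de_called: set[str] | None = None,
    rewired_called: set[str] | None = None,
    pairs_called: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Precision/recall per pipeline stage against the planted truth.

    Stages whose predictions are not supplied are omitted. Undefined
    precision (empty prediction) is reported as NaN.
    """
    rows = {}
    if de_called is not None:
        rows["de"] = _prf(set(de_called), set(truth.de_features))
    if rewired_called is not None:
        rows["rewired"] = _prf(set(rewired_called), set(truth.rewired_nodes))
    if pairs_called is not None:
        rows["gm_pairs"] = _prf(set(pairs_called), truth.gm_pair_keys())
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stage"
    return out.reset_index()
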