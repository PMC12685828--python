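"""Synthetic two-domain soil community generator with known truth.

Emulates the field-trial design — three cropping systems (W, S, SW) x
two sampling locations (bulk, rhizosphere) x blocks — for a bacterial
and a eukaryotic amplicon table, so that every downstream stage
(diversity, PERMANOVA, LEfSe, networks, dbRDA) has a recovery test with
planted ground truth.

Generative model, per domain:

* every taxon gets a base log-abundance ~ N(0, sigma_log^2); only a
  group-dependent "active" prefix of taxa is switched on, which plants
  alpha-diversity (Shannon) offsets of ln(richness multiplier);
* differential taxa receive a log-fold effect in the samples of their
  enriched treatment;
* per sample, correlated noise is added through a Gaussian copula:
  taxa inside a planted module share a latent factor so that each pair
  has latent correlation +/- rho (sign mix via per-taxon signs);
  everything else gets independent noise;
* counts are Dirichlet-multinomial: the sample's composition is
  softmax(latent), Dirichlet-perturbed with concentration 1/theta, then
  multinomially sampled at the design depth (theta = 0 gives plain
  multinomial counts), so column sums equal the depth exactly;
* soil variables are affine maps of the first two latent community
  gradients (left singular vectors of the centered bacterial latent
  matrix) plus Gaussian noise; unlinked variables are pure noise.

Correlation truth lives on the latent scale: the copula-implied rank
correlation of a module pair is (6/pi) * arcsin(rho/2), and count-scale
correlation is attenuated by compositional closure, sampling depth and
overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, ValidationError
from .tables_io import (
    FeatureTable,
    GROUP_ORDER,
    LOCATIONS,
    SOIL_VARIABLES,
    TREATMENTS,
    validate_metadata,
)

DOMAINS = ("bacterial", "eukaryotic")

#: Realistic per-variable (mean, sd) scales for the soil table, on the
#: order of the field trial's reported values.
SOIL_SCALES: dict[str, tuple[float, float]] = {
    "TP": (1.44, 0.12), "TN": (1.17, 0.08), "AP": (36.4, 4.0),
    "pH": (8.2, 0.15), "SOC": (8.94, 0.7), "Cs": (43.9, 8.0),
    "WSOC": (0.54, 0.10), "EOC": (1.56, 0.30), "SN": (24.9, 2.5),
    "urease": (67.9, 10.0), "sucrase": (1.35, 0.30), "Pm": (5.1, 2.0),
    "phosphatase": (78.8, 10.0), "catalase": (3.4, 0.3),
}


@dataclass(frozen=True)
class ModuleSpec:
    """A planted correlation module.

    ``treatment`` restricts the module to that treatment's samples
    (None = all samples); ``frac_negative`` of the members get a flipped
    sign, making their pairwise latent correlation -rho against the rest.
    """

    size: int
    rho: float
    treatment: str | None = None
    frac_negative: float = 0.0


@dataclass(frozen=True)
class DifferentialSpec:
    """Planted differential-abundance taxa (log-fold enriched in one
    treatment each, assigned round-robin over treatments)."""

    n: int = 40
    log_fold: float = math.log(4.0)


def copula_spearman(rho: float) -> float:
    """Spearman correlation implied by a Gaussian copula with
    correlation ``rho``: (6/pi) * arcsin(rho / 2)."""
    return (6.0 / math.pi) * math.asin(rho / 2.0)


@dataclass
class CommunityDesign:
    """Everything the generator needs; defaults are the field-trial
    ("paper-scale") conditions."""

    n_taxa: dict[str, int] = field(
        default_factory=lambda: {"bacterial": 600, "eukaryotic": 150}
    )
    depth: int = 30_000
    n_blocks: int = 3
    sigma_log: float = 1.5
    noise_sigma: float = 1.0
    theta: float = 0.02
    active_fraction: float = 0.5
    #: per-domain, per-treatment effective-richness multiplier (plants a
    #: ln(multiplier) Shannon offset); the intercropped system gets the
    #: boost, mirroring its higher bacterial diversity
    richness_multiplier: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"bacterial": {"SW": 2.0}, "eukaryotic": {}}
    )
    differential: dict[str, DifferentialSpec] = field(
        default_factory=lambda: {
            "bacterial": DifferentialSpec(n=40),
            "eukaryotic": DifferentialSpec(n=12),
        }
    )
    #: planted modules: bacterial densest under S, eukaryotic densest
    #: under SW, mirroring the reported network orderings
    modules: dict[str, list[ModuleSpec]] = field(
        default_factory=lambda: {
            "bacterial": [
                ModuleSpec(15, 0.9, "S"),
                ModuleSpec(12, 0.85, "S", frac_negative=0.3),
                ModuleSpec(12, 0.85, "SW", frac_negative=0.4),
                ModuleSpec(8, 0.8, "SW"),
                ModuleSpec(8, 0.8, "W"),
            ],
            "eukaryotic": [
                ModuleSpec(12, 0.9, "SW"),
                ModuleSpec(10, 0.85, "SW", frac_negative=0.4),
                ModuleSpec(8, 0.8, "S"),
                ModuleSpec(6, 0.75, "W"),
            ],
        }
    )
    #: variable -> (coefficient on gradient 1, on gradient 2), in SD
    #: units of the standardized variable
    env_links: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TP": (0.9, 0.0),
            "AP": (0.7, 0.0),
            "pH": (0.0, 0.7),
            "EOC": (0.5, 0.5),
        }
    )
    env_noise: float = 0.4
    seed: int | None = None

    def validate(self) -> None:
        if self.depth < 1_000:
            raise DesignError("sequencing depth must be >= 1,000")
        if self.n_blocks < 1:
            raise DesignError("need at least 1 block")
        if not 0 < self.active_fraction <= 1:
            raise DesignError("active_fraction must be in (0, 1]")
        for domain in DOMAINS:
            if domain not in self.n_taxa:
                raise DesignError(f"missing n_taxa for domain {domain!r}")
            n_t = self.n_taxa[domain]
            specs = self.modules.get(domain, [])
            for spec in specs:
                if not -1 < spec.rho < 1:
                    raise DesignError(f"module rho {spec.rho} outside (-1, 1)")
                if spec.treatment is not None and \
                        spec.treatment not in TREATMENTS:
                    raise DesignError(
                        f"module treatment {spec.treatment!r} unknown"
                    )
            if sum(s.size for s in specs) > n_t:
                raise DesignError(
                    f"{domain}: module sizes sum to "
                    f"{sum(s.size for s in specs)} > n_taxa {n_t}"
                )
            diff = self.differential.get(domain, DifferentialSpec(n=0))
            if not math.isfinite(diff.log_fold):
                raise DesignError("differential log-fold must be finite")
            for mult in self.richness_multiplier.get(domain, {}).values():
                if mult <= 0:
                    raise DesignError("richness multiplier must be > 0")
                if mult * self.active_fraction > 1.0 + 1e-9:
                    raise DesignError(
                        "richness multiplier activates more taxa than exist"
                    )

    @property
    def n_samples(self) -> int:
        return len(TREATMENTS) * len(LOCATIONS) * self.n_blocks


def paper_design(seed: int | None = None) -> CommunityDesign:
    """The 18-sample field-trial-scale design."""
    return CommunityDesign(seed=seed)


def test_scale_design(seed: int | None = None) -> CommunityDesign:
    """A smaller, better-powered design for recovery tests: fewer taxa,
    more blocks, near-multinomial counts."""
    return CommunityDesign(
        n_taxa={"bacterial": 240, "eukaryotic": 120},
        depth=20_000,
        n_blocks=8,
        theta=0.002,
        differential={
            "bacterial": DifferentialSpec(n=40),
            "eukaryotic": DifferentialSpec(n=12),
        },
        seed=seed,
    )


def null_design(seed: int | None = None) -> CommunityDesign:
    """No planted effects of any kind: exchangeable samples."""
    return CommunityDesign(
        n_taxa={"bacterial": 120, "eukaryotic": 60},
        depth=2_000,
        n_blocks=2,
        richness_multiplier={"bacterial": {}, "eukaryotic": {}},
        differential={
            "bacterial": DifferentialSpec(n=0),
            "eukaryotic": DifferentialSpec(n=0),
        },
        modules={"bacterial": [], "eukaryotic": []},
        env_links={},
        seed=seed,
    )


def differential_recovery_design(seed: int | None = None) -> CommunityDesign:
    """Test-scale design whose only planted mean structure is the 40
    bacterial differential taxa (no richness boost, which would itself
    make every taxon differential through dilution)."""
    design = test_scale_design(seed=seed)
    design.richness_multiplier = {"bacterial": {}, "eukaryotic": {}}
    return design


def module_recovery_design(seed: int | None = None) -> CommunityDesign:
    """One strong correlation module (rho=0.9, 15 taxa) in the
    intercropped system, 30 samples per treatment, near-multinomial
    counts: the condition for edge precision/recall recovery."""
    return CommunityDesign(
        n_taxa={"bacterial": 120, "eukaryotic": 20},
        depth=5_000,
        n_blocks=15,
        theta=0.0,
        richness_multiplier={"bacterial": {}, "eukaryotic": {}},
        differential={
            "bacterial": DifferentialSpec(n=0),
            "eukaryotic": DifferentialSpec(n=0),
        },
        modules={
            "bacterial": [ModuleSpec(15, 0.9, "SW")],
            "eukaryotic": [],
        },
        env_links={},
        seed=seed,
    )


def complexity_ranking_design(seed: int | None = None) -> CommunityDesign:
    """Test-scale design with extra blocks (24 samples per treatment) so
    the planted SW-densest eukaryotic module contrast is reliably
    detectable in the per-treatment networks."""
    design = test_scale_design(seed=seed)
    design.n_blocks = 12
    return design


PRESETS = {
    "paper": paper_design,
    "test": test_scale_design,
    "null": null_design,
}


@dataclass
class PlantedModule:
    domain: str
    treatment: str | None
    taxon_ids: list[str]
    rho: float
    signs: np.ndarray  # +/- 1 per member

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (self.taxon_ids[i], self.taxon_ids[j])
            for i in range(len(self.taxon_ids))
            for j in range(i + 1, len(self.taxon_ids))
        ]


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    differential: pd.DataFrame  # columns domain, taxon_id, enriched_treatment
    modules: list[PlantedModule]
    env_links: dict[str, tuple[float, float]]


@dataclass
class SimulationResult:
    feature_tables: dict[str, FeatureTable]
    metadata: pd.DataFrame
    soil: pd.DataFrame
    truth: SyntheticTruth
    latents: dict[str, np.ndarray]  # taxa x samples log-abundance
    design: CommunityDesign


def _make_metadata(design: CommunityDesign) -> pd.DataFrame:
    rows = []
    for treatment in TREATMENTS:
        for location in LOCATIONS:
            for block in range(1, design.n_blocks + 1):
                prefix = "R" if location == "rhizosphere" else "B"
                sid = f"{prefix}{treatment}{block}"
                rows.append((sid, treatment, location, block))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "treatment", "location", "block"]
    ).set_index("sample_id")
    return validate_metadata(meta)


def _simulate_domain(
    domain: str,
    design: CommunityDesign,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[FeatureTable, np.ndarray, pd.DataFrame, list[PlantedModule]]:
    n_t = design.n_taxa[domain]
    n_s = len(meta)
    taxon_ids = [f"{domain[:3].upper()}_ASV{i + 1:04d}" for i in range(n_t)]
    base = rng.normal(0.0, design.sigma_log, size=n_t)

    k0 = max(int(round(design.active_fraction * n_t)), 2)
    multipliers = design.richness_multiplier.get(domain, {})
    active_per_treatment = {
        t: min(int(round(multipliers.get(t, 1.0) * k0)), n_t)
        for t in TREATMENTS
    }

    # differential taxa: drawn from above-median base abundance within the
    # always-active core so the planted biomarkers are detectable in
    # principle; enriched treatment assigned round-robin
    diff_spec = design.differential.get(domain, DifferentialSpec(n=0))
    core = np.arange(k0)
    eligible = core[base[core] >= np.median(base[core])]
    if diff_spec.n > len(eligible):
        raise DesignError(
            f"{domain}: {diff_spec.n} differential taxa requested but only "
            f"{len(eligible)} eligible core taxa"
        )
    diff_idx = rng.choice(eligible, size=diff_spec.n, replace=False)
    # round-robin over abundance-sorted taxa balances the boosted share
    # across treatments, so the compositional denominators shift almost
    # equally and null taxa stay null on the relative scale
    diff_idx = diff_idx[np.argsort(-base[diff_idx])]
    diff_treatment = [TREATMENTS[i % 3] for i in range(diff_spec.n)]
    diff_rows = pd.DataFrame(
        {
            "domain": domain,
            "taxon_id": [taxon_ids[i] for i in diff_idx],
            "enriched_treatment": diff_treatment,
        }
    )
    effect = np.zeros((n_t, len(TREATMENTS)))
    for idx, treatment in zip(diff_idx, diff_treatment):
        effect[idx, TREATMENTS.index(treatment)] = diff_spec.log_fold

    # modules occupy disjoint mid-abundance core slots: abundant enough
    # to detect, but skipping the dominant taxa so the module never
    # carries a large share of the community -- a module that dominates
    # the total cancels out of the compositional denominator and its
    # correlation becomes unidentifiable on the count scale.  The
    # differential taxa are excluded so the two kinds of truth do not
    # overlap.
    specs = design.modules.get(domain, [])
    taken = set(int(i) for i in diff_idx)
    by_abundance = core[np.argsort(-base[core])]
    n_skip = max(3, k0 // 10)
    pool = [int(i) for i in by_abundance[n_skip:] if i not in taken]
    modules: list[PlantedModule] = []
    cursor = 0
    for spec in specs:
        if cursor + spec.size > len(pool):
            raise DesignError(
                f"{domain}: not enough free core taxa for module of size "
                f"{spec.size}"
            )
        members = pool[cursor: cursor + spec.size]
        cursor += spec.size
        signs = np.ones(spec.size)
        n_neg = int(round(spec.frac_negative * spec.size))
        if n_neg:
            signs[rng.choice(spec.size, size=n_neg, replace=False)] = -1.0
        modules.append(
            PlantedModule(
                domain=domain,
                treatment=spec.treatment,
                taxon_ids=[taxon_ids[i] for i in members],
                rho=spec.rho,
                signs=signs,
            )
        )

    member_index = [
        np.array([taxon_ids.index(t) for t in m.taxon_ids]) for m in modules
    ]

    latent = np.empty((n_t, n_s))
    counts = np.empty((n_t, n_s), dtype=np.int64)
    suppressed_level = -15.0  # effectively absent after softmax
    for s, (sid, row) in enumerate(meta.iterrows()):
        treatment = row["treatment"]
        z = rng.normal(0.0, 1.0, size=n_t)
        for spec, members, module in zip(specs, member_index, modules):
            shared = rng.normal()
            if module.treatment is None or module.treatment == treatment:
                z[members] = module.signs * (
                    math.sqrt(spec.rho) * shared
                    + math.sqrt(1.0 - spec.rho) * z[members]
                )
        x = base + effect[:, TREATMENTS.index(treatment)] \
            + design.noise_sigma * z
        n_active = active_per_treatment[treatment]
        x[n_active:] = suppressed_level
        latent[:, s] = x
        p = np.exp(x - x.max())  # softmax, shift-invariant
        p /= p.sum()
        if design.theta > 0:
            p = rng.dirichlet(p / design.theta)
        counts[:, s] = rng.multinomial(design.depth, p)

    table = FeatureTable(taxon_ids, list(meta.index), counts)
    return table, latent, diff_rows, modules


def _simulate_soil(
    design: CommunityDesign,
    meta: pd.DataFrame,
    latent: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_s = len(meta)
    centered = (latent - latent.mean(axis=1, keepdims=True)).T  # samples x taxa
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    gradients = np.zeros((n_s, 2))
    for axis in range(min(2, u.shape[1])):
        g = u[:, axis]
        sd = g.std()
        gradients[:, axis] = (g - g.mean()) / sd if sd > 0 else 0.0

    data = {}
    for var in SOIL_VARIABLES:
        mu, sd = SOIL_SCALES[var]
        b1, b2 = design.env_links.get(var, (0.0, 0.0))
        signal_var = b1 ** 2 + b2 ** 2
        noise_sd = math.sqrt(max(1.0 - signal_var, design.env_noise ** 2))
        standardized = (
            b1 * gradients[:, 0]
            + b2 * gradients[:, 1]
            + rng.normal(0.0, noise_sd, size=n_s)
        )
        data[var] = mu + sd * standardized
    return pd.DataFrame(data, index=meta.index)


def simulate_dataset(
    design: CommunityDesign | None = None, seed: int | None = None
) -> SimulationResult:
    """Generate the full two-domain dataset with planted truth.

    ``seed`` overrides ``design.seed``; the same seed gives bit-identical
    output.  Returns feature tables per domain, metadata, the soil table,
    the truth object and the latent log-abundance matrices.
    """
    design = design if design is not None else CommunityDesign()
    design.validate()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    meta = _make_metadata(design)

    tables: dict[str, FeatureTable] = {}
    latents: dict[str, np.ndarray] = {}
    diff_frames = []
    all_modules: list[PlantedModule] = []
    for domain in DOMAINS:
        table, latent, diff, modules = _simulate_domain(
            domain, design, meta, rng
        )
        tables[domain] = table
        latents[domain] = latent
        diff_frames.append(diff)
        all_modules.extend(modules)

    soil = _simulate_soil(design, meta, latents["bacterial"], rng)
    truth = SyntheticTruth(
        differential=pd.concat(diff_frames, ignore_index=True),
        modules=all_modules,
        env_links=dict(design.env_links),
    )
    return SimulationResult(
        feature_tables=tables,
        metadata=meta,
        soil=soil,
        truth=truth,
        latents=latents,
        design=design,
    )


def planted_diversity_offset(
    design: CommunityDesign, group: str, domain: str = "bacterial"
) -> float:
    """Analytic expected Shannon shift of ``group`` vs baseline.

    The generator plants evenness through the active-taxon count: a
    richness multiplier m makes the group's expected Shannon entropy
    higher by ln(m) in the infinite-depth, many-taxa limit (the
    lognormal evenness correction is shared and cancels).
    """
    if group not in GROUP_ORDER:
        raise ValidationError(
            f"unknown group {group!r}; allowed: {GROUP_ORDER}"
        )
    treatment = group[1:] if group.startswith("R") else group
    mult = design.richness_multiplier.get(domain, {}).get(treatment, 1.0)
    return math.log(mult)
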