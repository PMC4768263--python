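"""Synthetic pharmacogenomic screens with planted driver-modulator structure.

The generator emulates the statistical skeleton the discovery method
assumes, with full ground truth retained:

* binary alterations occur independently per cell, Bernoulli(freq);
* expression is Gaussian per gene, Normal(mu, tau^2);
* canonical sensitivity for a planted drug is

      y = beta0 + sum_d beta_d * alt_d + sum_m gamma_m * expr_m * alt_cond(m) + eps

  i.e. a *driver* alteration shifts sensitivity additively, and a
  *modulator*'s expression acts on sensitivity only within the cells
  carrying its conditioning driver; eps ~ Normal(0, sigma^2) i.i.d.

The response matrix is emitted in the scenario's declared orientation
(negated when the metric is lower-is-sensitive), so the generator can mimic
both activity-area-like and log-IC50-like screens.  Identical
(scenario, seed) always reproduces identical output (numpy PCG64 generator
seeded from the scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (AlterationFeature, DrugTargetTable, GeneSetCollection,
                 PharmacogenomicDataset, SensitivityMetric)
from .synergy import DoseResponsePoint

__all__ = ["DriverSpec", "ModulatorSpec", "SyntheticScenario", "GroundTruth",
           "generate", "default_scenario", "default_two_dataset_scenario",
           "default_support", "generate_dose_response"]


@dataclass(frozen=True)
class DriverSpec:
    """A planted driver: carriers of ``feature`` gain ``effect`` canonical
    sensitivity units (positive = sensitizing)."""

    feature: AlterationFeature
    effect: float


@dataclass(frozen=True)
class ModulatorSpec:
    """A planted modulator: within cells carrying ``conditioning_feature``,
    each expression unit of ``gene`` adds ``slope`` canonical units
    (negative = resistance modulator)."""

    gene: str
    conditioning_feature: AlterationFeature
    slope: float


@dataclass(frozen=True)
class SyntheticScenario:
    n_cells: int
    features: tuple[tuple[AlterationFeature, float], ...]  # (feature, freq)
    drivers: tuple[DriverSpec, ...]
    modulators: tuple[ModulatorSpec, ...]
    n_background_genes: int = 30
    expression_mean: float = 0.0
    expression_sd: float = 1.0
    noise_sd: float = 0.5
    baseline: float = 3.0
    drugs: tuple[str, ...] = ("drugX",)        # share the planted truth
    null_drugs: tuple[str, ...] = ()           # baseline + noise only
    metric: SensitivityMetric = field(
        default_factory=SensitivityMetric.activity_area)
    name: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        feat_set = {f for f, _ in self.features}
        for f, freq in self.features:
            if not 0.0 < freq < 1.0:
                raise ValueError(f"frequency for {f} must be in (0,1)")
        driver_feats = {d.feature for d in self.drivers}
        if not driver_feats <= feat_set:
            raise ValueError("every driver feature must be a declared feature")
        for m in self.modulators:
            if m.conditioning_feature not in driver_feats:
                raise ValueError(
                    f"modulator {m.gene}: conditioning feature "
                    f"{m.conditioning_feature} is not a declared driver"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.expression_sd <= 0:
            raise ValueError("expression_sd must be > 0")
        if not self.drugs and not self.null_drugs:
            raise ValueError("scenario declares no drugs")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth and per-cell generative components for auditing."""

    planted_pairs: tuple[tuple[AlterationFeature, str, str], ...]
    signal: dict[str, np.ndarray]   # drug -> noiseless canonical signal
    noise: dict[str, np.ndarray]    # drug -> eps draws


def generate(scenario: SyntheticScenario
             ) -> tuple[PharmacogenomicDataset, GroundTruth]:
    """Sample one screen from the scenario's generative model."""
    rng = np.random.default_rng(scenario.seed)
    cells = [f"CL{i:04d}" for i in range(scenario.n_cells)]

    feats = [f for f, _ in scenario.features]
    freqs = np.array([fr for _, fr in scenario.features])
    alt = (rng.random((len(feats), scenario.n_cells))
           < freqs[:, None]).astype(int)
    alt_df = pd.DataFrame(alt, index=[f.key for f in feats], columns=cells)

    mod_genes = sorted({m.gene for m in scenario.modulators})
    bg_genes = [f"BG{i:03d}" for i in range(scenario.n_background_genes)]
    genes = mod_genes + [g for g in bg_genes if g not in mod_genes]
    expr = rng.normal(scenario.expression_mean, scenario.expression_sd,
                      size=(len(genes), scenario.n_cells))
    expr_df = pd.DataFrame(expr, index=genes, columns=cells)
    gene_row = {g: i for i, g in enumerate(genes)}
    feat_row = {f: i for i, f in enumerate(feats)}

    signal = scenario.baseline * np.ones(scenario.n_cells)
    for d in scenario.drivers:
        signal = signal + d.effect * alt[feat_row[d.feature]]
    for m in scenario.modulators:
        gate = alt[feat_row[m.conditioning_feature]]
        signal = signal + m.slope * expr[gene_row[m.gene]] * gate

    resp_rows = {}
    noise_by_drug: dict[str, np.ndarray] = {}
    signal_by_drug: dict[str, np.ndarray] = {}
    for drug in scenario.drugs:
        eps = rng.normal(0.0, scenario.noise_sd, scenario.n_cells)
        y = signal + eps
        signal_by_drug[drug] = signal.copy()
        noise_by_drug[drug] = eps
        resp_rows[drug] = y if scenario.metric.higher_is_sensitive else -y
    for drug in scenario.null_drugs:
        eps = rng.normal(0.0, scenario.noise_sd, scenario.n_cells)
        y = scenario.baseline + eps
        signal_by_drug[drug] = np.full(scenario.n_cells, scenario.baseline)
        noise_by_drug[drug] = eps
        resp_rows[drug] = y if scenario.metric.higher_is_sensitive else -y

    resp_df = pd.DataFrame(resp_rows, columns=None).T
    resp_df.columns = cells

    dataset = PharmacogenomicDataset(
        alterations=alt_df, expression=expr_df, responses=resp_df,
        metric=scenario.metric, name=scenario.name,
    )
    truth = GroundTruth(
        planted_pairs=tuple(
            (m.conditioning_feature, m.gene, drug)
            for m in scenario.modulators for drug in scenario.drugs
        ),
        signal=signal_by_drug,
        noise=noise_by_drug,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# canonical study scenarios
# ---------------------------------------------------------------------------

#: defaults of the planted single driver-modulator study condition
DRIVER_GENE = "GD1"
MODULATOR_GENE = "MOD1"
DRIVER_FREQ = 0.35
DRIVER_EFFECT = 3.0
MODULATOR_SLOPE = -0.8
N_BACKGROUND_FEATURES = 20
BACKGROUND_FEATURE_FREQ = 0.2


def default_scenario(seed: int = 0,
                     n_cells: int = 200,
                     name: str = "synthetic",
                     metric: SensitivityMetric | None = None,
                     drugs: tuple[str, ...] = ("drugX",),
                     noise_sd: float = 0.5) -> SyntheticScenario:
    """The canonical single driver-modulator study condition.

    One sensitizing driver (GD1:MUT, frequency 0.35, effect +3 canonical
    units = 6 noise SDs) and one resistance modulator (MOD1, slope -0.8 per
    expression unit, active only in driver-altered cells), over 20 inert
    background alteration features and 30 background expression genes.
    """
    driver = AlterationFeature(DRIVER_GENE, "MUT")
    features = [(driver, DRIVER_FREQ)] + [
        (AlterationFeature(f"N{i:02d}", "MUT"), BACKGROUND_FEATURE_FREQ)
        for i in range(N_BACKGROUND_FEATURES)
    ]
    return SyntheticScenario(
        n_cells=n_cells,
        features=tuple(features),
        drivers=(DriverSpec(driver, DRIVER_EFFECT),),
        modulators=(ModulatorSpec(MODULATOR_GENE, driver, MODULATOR_SLOPE),),
        noise_sd=noise_sd,
        drugs=drugs,
        metric=metric if metric is not None
        else SensitivityMetric.activity_area(),
        name=name,
        seed=seed,
    )


def default_two_dataset_scenario(seed: int = 0
                                 ) -> tuple[SyntheticScenario, SyntheticScenario]:
    """Two screens sharing the planted truth with independent noise.

    They mimic a cross-validation pair: different drug names of the same
    target class and *opposite* metric orientations (activity-area-like vs
    ln-IC50-like).  Seeds are derived deterministically from ``seed``.
    """
    scen_a = default_scenario(seed=seed * 2 + 1, name="screen_A",
                              metric=SensitivityMetric.activity_area(),
                              drugs=("inhibA",))
    scen_b = default_scenario(seed=seed * 2 + 2, name="screen_B",
                              metric=SensitivityMetric.ln_ic50(),
                              drugs=("inhibB",))
    return scen_a, scen_b


def default_support(n_pathway_background: int = 19
                    ) -> tuple[GeneSetCollection, DrugTargetTable,
                               frozenset[str]]:
    """Annotation resources matching the canonical scenarios: a core-pathway
    collection containing the modulator plus background genes, a drug-target
    table mapping both screens' drug X to the driver gene and a drug Y to
    the modulator, and a common-cancer-gene list containing the driver."""
    pathway = GeneSetCollection({
        "CORE_PATHWAY": frozenset(
            [MODULATOR_GENE] + [f"BG{i:03d}"
                                for i in range(n_pathway_background)]
        ),
    })
    targets = DrugTargetTable(frozenset({
        ("inhibA", DRIVER_GENE),
        ("inhibB", DRIVER_GENE),
        ("drugX", DRIVER_GENE),
        ("drugY", MODULATOR_GENE),
    }))
    common = frozenset({DRIVER_GENE, "TP53", "KRAS", "BRAF"})
    return pathway, targets, common


def generate_dose_response(m: float, Dm: float, doses,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> list[DoseResponsePoint]:
    """Sample dose-response readings from a median-effect curve.

    Noise is multiplicative lognormal on the odds fa/(1-fa); fa is clipped
    to (1e-6, 1-1e-6) before constructing points.
    """
    if m == 0 or Dm <= 0:
        raise ValueError("need m != 0 and Dm > 0")
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0 or np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    odds = (doses / Dm) ** m
    if noise_sd > 0:
        odds = odds * np.exp(rng.normal(0.0, noise_sd, doses.size))
    fa = np.clip(odds / (1.0 + odds), 1e-6, 1.0 - 1e-6)
    return [DoseResponsePoint(float(d), float(f)) for d, f in zip(doses, fa)]
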