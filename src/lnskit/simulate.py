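"""Synthetic two-species expression compendia with planted ground truth.

The generator emulates the structure of a multi-dataset microarray
compendium: genes belong to co-expression modules; in each dataset every
module follows its own latent condition profile (one draw per array from
N(0, module_signal_sd^2)) and a gene's log-ratio is its module's profile
plus independent Gaussian measurement noise.  Species B shares the module
map except for a planted fraction of orthologs reassigned to a different
module — the neighbourhood swap that local network similarity is designed
to detect.  Missing values and replicate arrays are injected on request.
Everything is driven by a single seed, so identical specs reproduce
byte-identical fixtures.

Defaults mirror a desk-scale version of a real compendium: 300 genes in 10
modules, 6 datasets of 12 arrays per species, signal sd 1 against noise sd
0.7 (within-module correlation ~0.67), 5% missing cells, 10% of orthologs
divergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, OrthologMap


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-species compendium."""

    n_genes: int = 300
    n_modules: int = 10
    n_datasets: int = 6
    arrays_per_dataset: int = 12
    module_signal_sd: float = 1.0
    noise_sd: float = 0.7
    divergent_fraction: float = 0.1
    missing_rate: float = 0.05
    replicate_count: int = 1
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")
        for name in ("n_genes", "n_modules", "n_datasets",
                     "arrays_per_dataset", "replicate_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.divergent_fraction <= 1:
            raise ValueError("divergent_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_divergent(self) -> int:
        return round(self.divergent_fraction * self.n_genes)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic fixture."""

    module_a: dict[str, int] = field(default_factory=dict)
    module_b: dict[str, int] = field(default_factory=dict)
    divergent: list[str] = field(default_factory=list)  # species-A gene ids
    periodic_phases: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = []
        div = set(self.divergent)
        for g, m in self.module_a.items():
            rows.append({"gene_a": g, "module_a": m,
                         "module_b": self.module_b.get(g, m),
                         "divergent": int(g in div)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _simulate_datasets(modules: np.ndarray, gene_ids: list[str], species: str,
                       spec: SyntheticSpec, rng: np.random.Generator
                       ) -> list[ExpressionDataset]:
    datasets = []
    for d in range(spec.n_datasets):
        n_base = spec.arrays_per_dataset
        factors = rng.normal(0.0, spec.module_signal_sd,
                             size=(spec.n_modules, n_base))
        cols: dict[str, np.ndarray] = {}
        groups: dict[str, str] = {}
        for a in range(n_base):
            base = factors[modules, a]
            for r in range(spec.replicate_count):
                name = (f"a{a + 1}" if spec.replicate_count == 1
                        else f"a{a + 1}r{r + 1}")
                cols[name] = base + rng.normal(0.0, spec.noise_sd,
                                               size=spec.n_genes)
                if spec.replicate_count > 1:
                    groups[name] = f"a{a + 1}"
        values = pd.DataFrame(cols, index=gene_ids)
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) < spec.missing_rate
            values = values.mask(mask)
        datasets.append(ExpressionDataset(
            dataset_id=f"{species}_ds{d + 1}",
            values=values,
            replicate_groups=groups or None,
        ))
    return datasets


def generate_compendium(spec: SyntheticSpec | None = None
                        ) -> tuple[list[ExpressionDataset],
                                   list[ExpressionDataset],
                                   OrthologMap, SyntheticTruth]:
    """Generate matched species-A and species-B compendia with known truth.

    Returns (datasets_A, datasets_B, ortholog_map, truth).  Exactly
    ``round(divergent_fraction * n_genes)`` orthologs have their module
    membership reassigned in species B; the rest share their module across
    species.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    genes_a = _gene_ids("gA", spec.n_genes)
    genes_b = _gene_ids("gB", spec.n_genes)

    modules_a = rng.integers(0, spec.n_modules, size=spec.n_genes)
    modules_b = modules_a.copy()
    div_idx = rng.choice(spec.n_genes, size=spec.n_divergent, replace=False)
    div_idx.sort()
    for i in div_idx:
        if spec.n_modules > 1:
            shift = rng.integers(1, spec.n_modules)
            modules_b[i] = (modules_a[i] + shift) % spec.n_modules

    datasets_a = _simulate_datasets(modules_a, genes_a, "A", spec, rng)
    datasets_b = _simulate_datasets(modules_b, genes_b, "B", spec, rng)
    om = OrthologMap(list(zip(genes_a, genes_b)))
    truth = SyntheticTruth(
        module_a={g: int(m) for g, m in zip(genes_a, modules_a)},
        module_b={g: int(m) for g, m in zip(genes_a, modules_b)},
        divergent=[genes_a[i] for i in div_idx],
    )
    return datasets_a, datasets_b, om, truth


def generate_timecourse(n_genes: int = 100, n_periodic: int = 20,
                        n_timepoints: int = 16, cycles: int = 2,
                        noise_sd: float = 0.2, seed: int = 17,
                        dataset_id: str = "timecourse"
                        ) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Synchrony time-course fixture with planted periodic genes.

    Periodic genes follow ``cos(2*pi*cycles*t/T - phi)`` with uniform random
    phase phi plus Gaussian noise; the remaining genes are pure noise.  The
    planted phases are recorded in the returned truth.  Requires enough
    time points to resolve the cycle count (``n_timepoints >= 2*cycles+2``).
    """
    if n_periodic > n_genes:
        raise ValueError("n_periodic cannot exceed n_genes")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if n_timepoints < 2 * cycles + 2:
        raise ValueError(
            f"n_timepoints must be >= {2 * cycles + 2} to resolve "
            f"{cycles} cycles without aliasing"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_ids("g", n_genes)
    t = np.arange(n_timepoints)
    X = rng.normal(0.0, noise_sd, size=(n_genes, n_timepoints)) if noise_sd > 0 \
        else np.zeros((n_genes, n_timepoints))
    phases = rng.uniform(0.0, 2 * np.pi, size=n_periodic)
    per_idx = rng.choice(n_genes, size=n_periodic, replace=False)
    per_idx.sort()
    for j, i in enumerate(per_idx):
        X[i] += np.cos(2 * np.pi * cycles * t / n_timepoints - phases[j])
    values = pd.DataFrame(X, index=genes,
                          columns=[f"t{i + 1}" for i in range(n_timepoints)])
    truth = SyntheticTruth(
        periodic_phases={genes[i]: float(phases[j])
                         for j, i in enumerate(per_idx)}
    )
    return ExpressionDataset(dataset_id=dataset_id, values=values), truth
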