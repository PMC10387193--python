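"""Synthetic expression data with planted biomarkers and a matched network.

The generator emulates the statistical setting the pipeline targets: a
binary case/control phenotype, gene modules whose members co-express,
and a minority of truly associated genes.  The model is a latent-factor
one — chosen because it makes the implied correlations analytic:

    x_gs = loading * F_{m(g), s} + effect_size * y_s * [g planted] + eps_gs

with F a standard-normal per-sample module factor, y the 0/1 label and
eps ~ N(0, noise_sd^2) i.i.d.  Within a module the expected Pearson
correlation of two genes is rho = loading^2 / (loading^2 + noise_sd^2);
the planted case/control mean shift is effect_size in units of noise_sd
(noise_sd defaults to 1).  The default loading of 1/sqrt(3) gives
rho = 0.25, a moderate co-expression typical of real modules; because
the module factor is common to all planted genes, the separation of the
first principal component of a planted signature is analytically
d' = effect_size / sqrt(rho + 1/n_biomarkers), so rho also controls how
much of the planted signal survives into component-level evaluation.  The companion network draws edges with
probability ``module_density`` within a module and
``background_density`` across, weighted by the respective expected
correlations, so edges concentrate where co-expression actually lives.

The defaults (500 genes, 400 samples, 30% cases, 20 planted biomarkers
in one module, effect size 1.5) are the scale at which the end-to-end
recovery properties of the pipeline are asserted.

What this generator does NOT emulate: RNA-seq count distributions
(expression is Gaussian — the pipeline consumes normalized expression,
so that suffices), batch effects, and correlated noise across modules.
A green recovery test therefore establishes the pipeline's statistical
machinery, not robustness to sequencing artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import GeneNetwork

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "make_dataset",
    "make_worked_fixture",
    "make_bridge_instance",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal world.

    ``effect_size`` is the case-minus-control mean shift of planted
    genes in units of ``noise_sd``; ``module_loading`` sets within-
    module correlation (rho = loading^2 / (loading^2 + noise_sd^2),
    0.25 at the defaults).  Planted biomarkers are the first
    ``n_biomarkers`` genes of module 0.
    """

    n_genes: int = 500
    n_samples: int = 400
    n_cases: int = 120
    n_biomarkers: int = 20
    effect_size: float = 1.5
    n_modules: int = 10
    module_density: float = 0.3
    background_density: float = 0.01
    noise_sd: float = 1.0
    module_loading: float = 3**-0.5  # within-module correlation 0.25
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not 0 < self.n_cases < self.n_samples:
            problems.append("n_cases must satisfy 0 < n_cases < n_samples")
        if self.n_modules < 1 or self.n_modules > self.n_genes:
            problems.append("n_modules must be in [1, n_genes]")
        if self.n_biomarkers > self.n_genes // self.n_modules:
            problems.append("biomarkers must fit inside one module")
        if self.effect_size < 0:
            problems.append("effect_size must be >= 0")
        if not (0 <= self.module_density <= 1 and 0 <= self.background_density <= 1):
            problems.append("densities must lie in [0, 1]")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @property
    def within_module_corr(self) -> float:
        lo2 = self.module_loading**2
        return lo2 / (lo2 + self.noise_sd**2)


@dataclass
class SyntheticDataset:
    """Generated bundle: expression, labels, network and the planted truth."""

    expr: pd.DataFrame
    labels: pd.Series
    network: GeneNetwork
    truth: dict

    @property
    def biomarkers(self) -> list[str]:
        return list(self.truth["biomarkers"])

    def write(self, outdir) -> None:
        """Dump the TSV/JSON files the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
        self.labels.rename("label").to_csv(
            outdir / "labels.tsv", sep="\t", index_label="sample_id"
        )
        self.network.write(outdir / "network.tsv", outdir / "nodes.tsv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _module_assignment(spec: SyntheticSpec) -> np.ndarray:
    """Round-robin-free contiguous blocks: gene g -> module g * M // G."""
    return (np.arange(spec.n_genes) * spec.n_modules) // spec.n_genes


def make_dataset(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    """Generate the expression matrix, labels, network and truth record.

    Fully deterministic given ``spec.seed``; all randomness flows
    through one local generator (no global state).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g, n = spec.n_genes, spec.n_samples

    gene_ids = pd.Index([f"G{i:04d}" for i in range(g)], name="gene_id")
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    modules = _module_assignment(spec)
    biomarker_mask = np.zeros(g, dtype=bool)
    module0 = np.flatnonzero(modules == 0)
    biomarker_mask[module0[: spec.n_biomarkers]] = True

    # labels: first n_cases samples are cases, then shuffled for realism
    y = np.zeros(n, dtype=int)
    y[: spec.n_cases] = 1
    rng.shuffle(y)

    factors = rng.standard_normal((spec.n_modules, n))  # per-sample module factors
    noise = rng.standard_normal((g, n)) * spec.noise_sd
    x = spec.module_loading * factors[modules] + noise
    x[biomarker_mask] += spec.effect_size * spec.noise_sd * y

    expr = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    labels = pd.Series(y, index=sample_ids, name="label")

    network = _module_network(spec, modules, gene_ids, rng)
    truth = {
        "biomarkers": list(gene_ids[biomarker_mask]),
        "modules": {gid: int(m) for gid, m in zip(gene_ids, modules)},
        "spec": asdict(spec),
        "within_module_corr": spec.within_module_corr,
    }
    return SyntheticDataset(expr, labels, network, truth)


def _module_network(
    spec: SyntheticSpec, modules: np.ndarray, gene_ids: pd.Index, rng
) -> GeneNetwork:
    """Edges within modules at module_density, across at background_density.

    Weights track the expected correlation: within-module edges carry
    rho = within_module_corr, cross-module edges a nominal 0.05 (genes
    in different modules are uncorrelated in the model; the faint cross
    edges emulate false-positive associations real networks contain).
    """
    g = len(gene_ids)
    same = modules[:, None] == modules[None, :]
    u = rng.random((g, g))
    u = np.triu(u, k=1)
    w_within = spec.within_module_corr
    w_cross = 0.05
    upper = np.triu(np.ones((g, g), dtype=bool), k=1)
    adj = np.zeros((g, g))
    adj[upper & same & (u < spec.module_density) & (u > 0)] = w_within
    adj[upper & ~same & (u < spec.background_density) & (u > 0)] = w_cross
    adj = adj + adj.T
    return GeneNetwork(gene_ids, sp.csr_matrix(adj))


_WORKED_SEED = 20230729  # fixed: the worked fixture is a constant of the package


def make_worked_fixture() -> dict:
    """Tiny deterministic bundle for docs and golden tests.

    Returns a dict with:

    - ``dataset``: a 20-gene x 30-sample :class:`SyntheticDataset`
      (10 cases, 4 planted biomarkers, strong effect) with no planted
      defects, so it passes cleaning unchanged;
    - ``two_node``: the 2-gene network A-B with one unit edge, whose
      fixed point at d = 0.5 with prior s = (1, 0) is exactly
      (2/3, 1/3);
    - ``two_node_prior``: that prior as a frame;
    - ``five_node``: a 5-gene weighted path-plus-chord network for
      hand-checkable propagation examples.
    """
    spec = SyntheticSpec(
        n_genes=20,
        n_samples=30,
        n_cases=10,
        n_biomarkers=4,
        effect_size=2.5,
        n_modules=4,
        module_density=0.6,
        background_density=0.05,
        seed=_WORKED_SEED,
    )
    dataset = make_dataset(spec)

    two_node = GeneNetwork.from_edges(["A", "B"], ["A"], ["B"], [1.0])
    two_node_prior = pd.DataFrame(
        {"raw_r": [1.0, 0.0], "s": [1.0, 0.0], "p_value": [0.0, 1.0]},
        index=pd.Index(["A", "B"], name="gene_id"),
    )

    five = ["N1", "N2", "N3", "N4", "N5"]
    five_node = GeneNetwork.from_edges(
        five,
        ["N1", "N2", "N3", "N4", "N1"],
        ["N2", "N3", "N4", "N5", "N3"],
        [0.5, 1.0, 0.25, 0.75, 0.4],
    )
    return {
        "dataset": dataset,
        "two_node": two_node,
        "two_node_prior": two_node_prior,
        "five_node": five_node,
    }


def make_bridge_instance() -> tuple[GeneNetwork, pd.DataFrame]:
    """Constructed instance showing the network advantage of propagation.

    Two genes share an identical moderate prior: ``BRIDGE`` is wired to
    three high-prior hub genes, ``LONER`` is isolated.  Pure correlation
    ranking ties them; damped propagation (d > 0) pulls score into
    ``BRIDGE`` through its neighborhood, so it must outrank ``LONER`` —
    the mechanism that favors genes both associated with the phenotype
    and connected to other significant genes.
    """
    nodes = ["HUB1", "HUB2", "HUB3", "BRIDGE", "LONER"]
    net = GeneNetwork.from_edges(
        nodes,
        ["BRIDGE", "BRIDGE", "BRIDGE", "HUB1", "HUB2"],
        ["HUB1", "HUB2", "HUB3", "HUB2", "HUB3"],
        [0.9, 0.9, 0.9, 0.8, 0.8],
    )
    s = np.array([0.9, 0.9, 0.9, 0.3, 0.3])
    prior = pd.DataFrame(
        {"raw_r": s, "s": s, "p_value": np.full(5, 1e-4)},
        index=pd.Index(nodes, name="gene_id"),
    )
    return net, prior
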