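"""Ground-truth-known synthetic data emulating a genome-reduction study.

The generator emulates the statistical structure of a bacterial
transcriptome experiment crossing a wild-type and a reduced genome (N0 /
N28) with environmental stressors (threonine, chloramphenicol) and
experimental evolution: ~4,000 genes on a circular ~4.6-Mb chromosome,
log10-scale expression carrying a six-cycle spatial cosine, sparse
per-gene perturbation effects whose dual-perturbation combination is
scaled by a built-in epistasis coefficient, block-correlated co-expression
modules (one tied to the growth rate), replicate noise, count sampling,
and logistic OD600 growth curves read every 30 min for 48 h.

Every generated dataset is paired with a :class:`SyntheticTruth` recording
all generating values, so downstream expected values are computable
without rerunning the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import FunctionMap
from .growth import GrowthCurve

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "generate_annotation",
    "generate_expression",
    "generate_counts",
    "generate_growth_curves",
    "generate_function_maps",
    "BASELINE_CONDITION",
]

#: reference condition of all perturbation contrasts
BASELINE_CONDITION = "N0-none-anc"

#: study-scale module sizes (11 modules spanning 30-1,118 genes; the
#: growth-linked module holds 271 genes, index 3)
DEFAULT_MODULE_SIZES = (1118, 600, 450, 271, 350, 200, 150, 100, 80, 50, 30)


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic study.

    Expression is generated on the log10 scale:
    ``baseline + amp*cos(2*pi*n_periods*x/L + phase) + condition effects +
    module factors + N(0, noise_sd)``.  For conditions combining two or
    more perturbations the built-in effect is
    ``alpha_true * (sum of single effects)``.
    """

    n_genes: int = 4000
    genome_length: float = 4_600_000
    n_periods: int = 6
    amp: float = 0.3
    phase: float = 0.0
    baseline: float = 2.0
    alpha_true: float = 0.6
    effect_sd_G: float = 1.0
    effect_sd_S: float = 1.0
    effect_sd_E: float = 1.0
    frac_affected_G: float = 0.4
    frac_affected_S: float = 0.4
    frac_affected_E: float = 0.4
    n_modules: int = 0
    module_sizes: tuple = ()
    growth_module_index: int | None = None
    module_strength: float = 1.0
    noise_sd: float = 0.2
    replicates: int = 3
    stresses: tuple = ("Thr", "Cm")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules and not self.module_sizes:
            self.module_sizes = DEFAULT_MODULE_SIZES[: self.n_modules]
        if self.module_sizes and not self.n_modules:
            self.n_modules = len(self.module_sizes)
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the number of genes")
        for f in (self.frac_affected_G, self.frac_affected_S, self.frac_affected_E):
            if not 0 <= f <= 1:
                raise ValueError("affected fractions must lie in [0, 1]")
        if self.genome_length <= 0 or self.n_periods < 1:
            raise ValueError("invalid genome_length or n_periods")


@dataclass
class SyntheticTruth:
    """Everything the generator drew, sufficient for all expected values."""

    design: SyntheticDesign
    annotation: pd.DataFrame = field(repr=False)
    design_table: pd.DataFrame = field(repr=False)
    effects: dict = field(repr=False)  # name -> per-gene vector
    module_labels: np.ndarray = field(repr=False)  # 0 = no module
    factors: pd.DataFrame = field(repr=False)  # samples x modules
    loadings: np.ndarray = field(repr=False)
    growth_rate: dict = field(repr=False)  # condition -> mu (1/h)

    def condition_effect(self, condition: str) -> np.ndarray:
        """Built-in per-gene log10 effect of a condition vs the baseline."""
        genome, stress, evo = condition.split("-")
        active = []
        if genome == "N28":
            active.append(self.effects["G"])
        if stress != "none":
            active.append(self.effects[f"S_{stress}"])
        if evo == "evo":
            active.append(self.effects["E"])
        if not active:
            return np.zeros(self.design.n_genes)
        total = np.sum(active, axis=0)
        return total if len(active) == 1 else self.design.alpha_true * total

    def true_delta(self, cond_from: str, cond_to: str) -> np.ndarray:
        return self.condition_effect(cond_to) - self.condition_effect(cond_from)

    def true_deg_flags(self, cond_from: str, cond_to: str) -> np.ndarray:
        return self.true_delta(cond_from, cond_to) != 0


def generate_annotation(
    n_genes: int, genome_length: float, seed: int | None = None
) -> pd.DataFrame:
    """Non-overlapping gene annotation on a circular chromosome.

    Genes occupy jittered positions within regular slots of the chromosome;
    returns a BED-like table (chrom, start, end, gene_id, score, strand)
    plus midpoint and length convenience columns.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if genome_length < n_genes * 100:
        raise ValueError(
            f"cannot pack {n_genes} genes of >= 50 bp with margins into "
            f"{genome_length:.0f} bp"
        )
    rng = np.random.default_rng(seed)
    slot = genome_length / n_genes
    lengths = np.maximum(rng.uniform(0.5, 0.9, n_genes) * slot, 50.0)
    starts = np.arange(n_genes) * slot + rng.uniform(0, 0.08, n_genes) * slot
    ends = np.minimum(starts + lengths, (np.arange(n_genes) + 1) * slot)
    starts, ends = np.floor(starts).astype(int), np.floor(ends).astype(int)
    ends = np.maximum(ends, starts + 50)  # enforce the 50-bp length floor
    annot = pd.DataFrame(
        {
            "chrom": "chr",
            "start": starts,
            "end": ends,
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "score": 0,
            "strand": rng.choice(["+", "-"], n_genes),
        }
    )
    annot["length"] = annot["end"] - annot["start"]
    annot["midpoint"] = (annot["start"] + annot["end"]) / 2.0 % genome_length
    return annot


def _condition_table(design: SyntheticDesign) -> pd.DataFrame:
    rows = []
    for genome in ("N0", "N28"):
        for stress in ("none", *design.stresses):
            for evo in ("anc", "evo"):
                cond = f"{genome}-{stress}-{evo}"
                for r in range(1, design.replicates + 1):
                    rows.append(
                        {
                            "sample": f"{cond}_r{r}",
                            "genome": genome,
                            "stress": stress,
                            "evolved": evo,
                            "replicate": r,
                            "condition": cond,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample")


def _true_growth_rates(design: SyntheticDesign) -> dict:
    """Deterministic per-condition growth rates (1/h).

    Genome reduction and each stressor multiply the rate down (~25-30%
    each, echoing the stress-concentration criterion); evolution partially
    restores it.
    """
    out = {}
    for genome in ("N0", "N28"):
        for stress in ("none", *design.stresses):
            for evo in ("anc", "evo"):
                mu = 0.7
                if genome == "N28":
                    mu *= 0.75
                if stress != "none":
                    mu *= 0.70
                if evo == "evo":
                    mu *= 1.15
                out[f"{genome}-{stress}-{evo}"] = round(mu, 6)
    return out


def _sparse_effects(rng, n_genes: int, frac: float, sd: float) -> np.ndarray:
    eff = np.zeros(n_genes)
    n_hit = int(round(frac * n_genes))
    if n_hit and sd > 0:
        hit = rng.choice(n_genes, size=n_hit, replace=False)
        eff[hit] = rng.normal(0.0, sd, n_hit)
    return eff


def generate_expression(design: SyntheticDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Log10 expression matrix (genes x samples) plus its generating truth."""
    rng = np.random.default_rng(design.seed)
    annot = generate_annotation(design.n_genes, design.genome_length, seed=design.seed)
    table = _condition_table(design)
    n, samples = design.n_genes, table.index.to_list()

    spatial = design.baseline + design.amp * np.cos(
        2 * np.pi * design.n_periods * annot["midpoint"].to_numpy()
        / design.genome_length
        + design.phase
    )

    effects = {"G": _sparse_effects(rng, n, design.frac_affected_G, design.effect_sd_G)}
    for s in design.stresses:
        effects[f"S_{s}"] = _sparse_effects(
            rng, n, design.frac_affected_S, design.effect_sd_S
        )
    effects["E"] = _sparse_effects(rng, n, design.frac_affected_E, design.effect_sd_E)

    growth = _true_growth_rates(design)
    trait = np.array([growth[c] for c in table["condition"]])

    # module structure: labels (1-based, 0 = none), per-sample factors,
    # positive per-gene loadings
    module_labels = np.zeros(n, dtype=int)
    loadings = np.zeros(n)
    n_samples = len(samples)
    factors = np.zeros((n_samples, design.n_modules))
    if design.n_modules:
        perm = rng.permutation(n)
        pos = 0
        for m, size in enumerate(design.module_sizes, start=1):
            idx = perm[pos : pos + size]
            module_labels[idx] = m
            loadings[idx] = rng.uniform(0.5, 1.0, size) * design.module_strength
            pos += size
        z_trait = (trait - trait.mean()) / trait.std()
        for m in range(design.n_modules):
            if design.growth_module_index is not None and m == design.growth_module_index:
                # growth-linked factor: monotone in the condition growth rate
                factors[:, m] = z_trait
            else:
                f = rng.normal(0.0, 1.0, n_samples)
                # exact ground truth "not growth-linked": remove any sample
                # correlation with the trait
                f = f - f.mean() - (f @ z_trait) / (z_trait @ z_trait) * z_trait
                factors[:, m] = f / f.std()

    truth = SyntheticTruth(
        design=design,
        annotation=annot,
        design_table=table,
        effects=effects,
        module_labels=module_labels,
        factors=pd.DataFrame(
            factors, index=samples, columns=[f"F{m+1}" for m in range(design.n_modules)]
        ),
        loadings=loadings,
        growth_rate=growth,
    )

    expr = np.empty((n, n_samples))
    for j, sample in enumerate(samples):
        cond = table.loc[sample, "condition"]
        col = spatial + truth.condition_effect(cond)
        if design.n_modules:
            col = col + loadings * factors[j, module_labels - 1] * (module_labels > 0)
        if design.noise_sd > 0:
            col = col + rng.normal(0.0, design.noise_sd, n)
        expr[:, j] = col
    expr_df = pd.DataFrame(expr, index=annot["gene_id"].to_numpy(), columns=samples)
    return expr_df, truth


def generate_counts(
    log_expr: pd.DataFrame,
    gene_lengths,
    depth: float = 1e6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multinomial read counts with expectation ~ gene length x linear expression.

    ``log_expr`` is log10 expression; each sample's counts are one
    multinomial draw of size ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    lengths = np.asarray(gene_lengths, dtype=float)
    lin = 10.0 ** log_expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(lin)) or np.any(lin < 0):
        raise ValueError("expression must be finite with positive linear scale")
    rng = np.random.default_rng(seed)
    weights = lin * lengths[:, None]
    counts = np.empty_like(weights, dtype=np.int64)
    for j in range(weights.shape[1]):
        p = weights[:, j] / weights[:, j].sum()
        counts[:, j] = rng.multinomial(int(depth), p)
    return pd.DataFrame(counts, index=log_expr.index, columns=log_expr.columns)


def generate_growth_curves(
    mu: float,
    lag_h: float = 1.0,
    capacity: float | None = 1.0,
    noise_sd: float = 0.0,
    interval_min: float = 30.0,
    duration_h: float = 48.0,
    seed: int | None = None,
    n_replicates: int = 1,
    od0: float = 0.01,
    label: str = "",
) -> list[GrowthCurve]:
    """Logistic growth curves: lag, exponential phase at rate ``mu``, and
    saturation at ``capacity`` (``None`` = unbounded exponential), sampled
    at ``interval_min`` over ``duration_h`` with multiplicative log-normal
    noise.
    """
    if mu < 0 or interval_min <= 0:
        raise ValueError("mu must be >= 0 and interval_min positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    s = np.maximum(t - lag_h, 0.0)
    if capacity is None or np.isinf(capacity):
        od = od0 * np.exp(mu * s)
    else:
        od = capacity / (1.0 + (capacity / od0 - 1.0) * np.exp(-mu * s))
    curves = []
    for r in range(n_replicates):
        noisy = od * np.exp(rng.normal(0.0, noise_sd, t.size)) if noise_sd > 0 else od
        curves.append(GrowthCurve(times=t, od=noisy, label=f"{label}r{r+1}"))
    return curves


def generate_function_maps(
    genes,
    n_regulons: int = 53,
    n_categories: int = 20,
    regulon_sizes=None,
    category_sizes=None,
    planted: dict | None = None,
    odds_ratio: float = 5.0,
    seed: int | None = None,
) -> tuple[FunctionMap, FunctionMap]:
    """Random regulon and gene-category membership tables over ``genes``.

    ``planted`` maps category names (e.g. ``"GC03"`` or ``"TF12"``) to gene
    sets whose members are ``odds_ratio`` times likelier to be sampled into
    that category, planting a true enrichment.
    """
    genes = list(genes)
    n = len(genes)
    rng = np.random.default_rng(seed)
    if regulon_sizes is None:
        regulon_sizes = rng.integers(11, 81, n_regulons)
    if category_sizes is None:
        category_sizes = rng.integers(31, 301, n_categories)

    def sample(name: str, size: int) -> set:
        if size > n:
            raise ValueError(f"category {name}: requested size {size} > {n} genes")
        w = np.ones(n)
        if planted and name in planted:
            target = planted[name]
            w = np.array([odds_ratio if g in target else 1.0 for g in genes])
        p = w / w.sum()
        picked = rng.choice(n, size=size, replace=False, p=p)
        return {genes[i] for i in picked}

    regulons = FunctionMap(
        members={f"TF{i:02d}": sample(f"TF{i:02d}", int(s))
                 for i, s in enumerate(regulon_sizes, start=1)},
        kind="regulon",
    )
    categories = FunctionMap(
        members={f"GC{i:02d}": sample(f"GC{i:02d}", int(s))
                 for i, s in enumerate(category_sizes, start=1)},
        kind="gene_category",
    )
    return regulons, categories


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the generating values (JSON; arrays as lists)."""
    payload = {
        "design": asdict(truth.design),
        "effects": {k: v.tolist() for k, v in truth.effects.items()},
        "module_labels": truth.module_labels.tolist(),
        "loadings": truth.loadings.tolist(),
        "factors": truth.factors.to_dict(orient="list"),
        "growth_rate": truth.growth_rate,
    }
    Path(path).write_text(json.dumps(payload))
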