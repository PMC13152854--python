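"""Synthetic stage-resolved dormancy transcriptomes with planted structure.

The generator emulates the reference study design — four peach cultivars
(two low- and two high-chilling-requirement), three endodormancy stages
(S1 induction, S2 maintenance, S3 release), three biological replicates —
and plants every structure the downstream analyses are supposed to recover:

* a dominant, approximately rank-one cultivar baseline (so cultivar
  background separates on PC1 while stage progression falls on PC2);
* eight unit temporal archetypes over the stages, assigned to genes, so
  k-means trajectory clustering has a known truth labelling;
* High-minus-Low CR offsets concentrated in designated archetypes, with a
  stage window (strong at the planted peak stage, weaker and opposite in
  sign elsewhere) so divergence statistics, directional discordance and
  peak-stage recovery are all testable;
* replicate-level latent factors shared by designated gene blocks, giving
  known co-expression modules that survive stage residualization;
* an ABA series driven by the mean expression of one archetype's genes
  (peaking at S2), a GA7 series rising sharply at the last stage, and a
  stage-varying GA3 series.

Expression is built on the log2(TPM+1) scale and transformed back with
``TPM = 2**x - 1`` (clipped at zero), so replicate noise is Normal on the
log scale (log-normal TPM).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AnnotationTable,
    ExpressionMatrix,
    FUNCTIONAL_CLASSES,
    validate_design,
    validate_hormones,
    write_annotation_table,
    write_expression,
    write_tsv,
)

REFERENCE_CULTIVARS = (("NG", "Low"), ("NS", "Low"), ("CM", "High"), ("ZY", "High"))
REFERENCE_STAGES = ("S1", "S2", "S3")

#: Default functional-class frequencies (regulatory classes are the minority,
#: as in genome-scale annotation).
DEFAULT_CLASS_PROBS = {
    "TF": 0.08,
    "kinase-related": 0.08,
    "hormone-associated": 0.08,
    "chromatin/RNA": 0.06,
    "other": 0.70,
}


def default_archetypes(n_stages: int, n_archetypes: int = 8) -> np.ndarray:
    """Unit temporal archetypes: points on the circle spanned by the linear
    and quadratic stage contrasts.

    Each row has zero mean and unit standard deviation (ddof=1) across
    stages.  For three stages the eight defaults include monotone rising and
    falling shapes, an S2 peak and an S2 trough, and four intermediates.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    t = np.arange(n_stages, dtype=float)
    e1 = t - t.mean()
    e1 /= e1.std(ddof=1)
    if n_stages == 2:
        return np.stack([e1, -e1])[:n_archetypes]
    e2 = -((t - t.mean()) ** 2)        # negated: mid-course peak, not trough
    e2 -= e2.mean()
    # orthogonalize against the linear contrast, then scale to unit sd
    e2 -= (e2 @ e1) / (e1 @ e1) * e1
    e2 /= e2.std(ddof=1)
    angles = 2 * np.pi * np.arange(n_archetypes) / n_archetypes
    arch = np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2
    return arch


@dataclass(frozen=True)
class PlantedDivergence:
    """High-minus-Low offset window for one divergent archetype.

    ``peak_offset`` (log2 units) is added to high-CR cultivars at
    ``peak_stage``; ``off_offset`` (opposite sign by default) at the other
    stages, which makes the planted genes directionally discordant.
    Per-gene magnitudes are scaled by Uniform(*gene_scale*) draws so the
    cluster-level mean divergence lands in a realistic sub-0.5 range.
    """

    peak_stage: str
    peak_offset: float = 0.8
    off_offset: float = -0.2


def _default_divergent_modules() -> dict[int, PlantedDivergence]:
    return {
        0: PlantedDivergence("S3"),   # rising archetype, late-window divergence
        1: PlantedDivergence("S2"),   # S2-peaking archetype, mid-window
        3: PlantedDivergence("S1"),   # falling archetype, early-window
    }


@dataclass
class TruthSpec:
    """Parameters of the planted generative model (the study conditions)."""

    n_genes: int = 2000
    cultivars: tuple[tuple[str, str], ...] = REFERENCE_CULTIVARS
    stages: tuple[str, ...] = REFERENCE_STAGES
    reps: int = 3
    archetypes: np.ndarray | None = None
    archetype_weights: tuple[float, ...] | None = None
    divergent_modules: dict[int, PlantedDivergence] = field(
        default_factory=_default_divergent_modules)
    divergence_gene_scale: tuple[float, float] = (0.35, 0.8)
    gene_mean_loc: float = 5.0
    gene_mean_scale: float = 2.0
    baseline_sd: float = 1.5
    cultivar_jitter_sd: float = 0.3
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.2
    hormone_module: int = 1
    aba_coupling: float = 40.0
    aba_noise_sd: float = 5.0
    ga_noise_sd: float = 0.3
    coexpr_blocks: tuple[int, ...] = (1, 3)
    coexpr_loading: tuple[float, float] = (0.7, 1.1)
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.reps < 1:
            raise ValueError("reps must be positive")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        if self.archetypes is None:
            self.archetypes = default_archetypes(len(self.stages))
            if self.archetype_weights is None and len(self.archetypes) == 8:
                # favour the monotone shapes so the linear stage contrast
                # dominates the quadratic one (stage ordering on one PC)
                self.archetype_weights = (0.2, 0.1, 0.1, 0.1, 0.2, 0.1, 0.1, 0.1)
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        if self.archetypes.shape[1] != len(self.stages):
            raise ValueError("archetypes must have one column per stage")
        for i, a in enumerate(self.archetypes):
            if abs(a.mean()) > 1e-8:
                raise ValueError(f"archetype {i} is not zero-mean")
            sd = a.std(ddof=1)
            if not (abs(sd - 1.0) < 1e-8 or sd < 1e-12):
                raise ValueError(f"archetype {i} must have unit sd (or be flat)")
        if self.archetype_weights is None:
            self.archetype_weights = tuple(
                1.0 / len(self.archetypes) for _ in self.archetypes)
        if len(self.archetype_weights) != len(self.archetypes):
            raise ValueError("one weight per archetype required")
        n_arch = len(self.archetypes)
        if not 0 <= self.hormone_module < n_arch:
            raise ValueError(f"unknown hormone_module {self.hormone_module}")
        for m, pd_ in self.divergent_modules.items():
            if not 0 <= m < n_arch:
                raise ValueError(f"unknown divergent module {m}")
            if pd_.peak_stage not in self.stages:
                raise ValueError(f"unknown peak stage {pd_.peak_stage!r}")
            if not (np.isfinite(pd_.peak_offset) and np.isfinite(pd_.off_offset)):
                raise ValueError("planted offsets must be finite")
        for b in self.coexpr_blocks:
            if not 0 <= b < n_arch:
                raise ValueError(f"unknown co-expression block archetype {b}")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if set(self.class_probs) - set(FUNCTIONAL_CLASSES):
            raise ValueError("class_probs keys must be in the class vocabulary")

    @property
    def n_archetypes(self) -> int:
        return len(self.archetypes)

    def design(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{c}_{s}_r{r}", "cultivar": c, "stage": s,
             "replicate": r, "cr_group": g}
            for c, g in self.cultivars
            for s in self.stages
            for r in range(1, self.reps + 1)
        ]
        return validate_design(pd.DataFrame(rows))


@dataclass
class SyntheticDataset:
    """A generated dataset plus the planted truth used by recovery tests."""

    expression: ExpressionMatrix
    hormones: pd.DataFrame
    annotations: AnnotationTable
    truth: pd.DataFrame          # per gene: archetype, amplitude, offsets...
    spec: TruthSpec
    aba_coupling: float

    def genes_of_archetype(self, archetype: int) -> pd.Index:
        return self.truth.index[self.truth["archetype"] == archetype]


def _cultivar_scores(cultivars: Sequence[tuple[str, str]]) -> np.ndarray:
    """Rank-one cultivar baseline scores, balanced across CR groups.

    Scores are equally spaced in [-1.5, 1.5] (full genotype spread for the
    PC1 background effect) but symmetric (+/-) pairs are dealt to one CR
    group at a time, so each group's mean score is zero and the baseline
    cancels exactly from the High-minus-Low contrast — mirroring a design
    where genetic background is not aligned with the CR phenotype.
    """
    n = len(cultivars)
    if n == 1:
        return np.zeros(1)
    base = list(np.linspace(-1.5, 1.5, n))
    members = {"Low": [i for i, (_, g) in enumerate(cultivars) if g == "Low"],
               "High": [i for i, (_, g) in enumerate(cultivars) if g == "High"]}
    scores = np.full(n, np.nan)
    turn = 0
    while len(base) >= 2 and max(len(members["Low"]), len(members["High"])) >= 2:
        grp = ("Low", "High")[turn % 2]
        if len(members[grp]) < 2:
            grp = ("Low", "High")[(turn + 1) % 2]
        scores[members[grp].pop(0)] = base.pop(0)
        scores[members[grp].pop(0)] = base.pop(-1)
        turn += 1
    for i in members["Low"] + members["High"]:
        scores[i] = base.pop(0)
    return scores


def _allocate_archetypes(spec: TruthSpec) -> np.ndarray:
    """Deterministic proportional allocation of genes to archetypes."""
    w = np.asarray(spec.archetype_weights, dtype=float)
    w = w / w.sum()
    counts = np.floor(w * spec.n_genes).astype(int)
    # hand the remainder to the largest fractional parts (ties -> low index)
    frac = w * spec.n_genes - counts
    for i in np.argsort(-frac, kind="stable")[: spec.n_genes - counts.sum()]:
        counts[i] += 1
    return np.repeat(np.arange(spec.n_archetypes), counts)


def generate_dataset(spec: TruthSpec) -> SyntheticDataset:
    """Generate expression + hormones + annotations with known truth.

    The log2(TPM+1) value for gene g (archetype a) in cultivar c, stage s,
    replicate r is::

        x = m_g + beta_g * t_c + jitter_gc
            + amplitude_g * archetype_a(s)
            + [c is high-CR and a divergent] * u_g * window_a(s)
            + loading_g * f_block(c, s, r)        (replicate-centred factor)
            + Normal(0, noise_sd)

    and ``TPM = max(2**x - 1, 0)``.  ``t_c`` is an equally spaced cultivar
    score, so the cultivar baseline is rank-one plus independent jitter.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_expr, rng_horm, rng_ann = [np.random.default_rng(s) for s in ss.spawn(3)]

    design = spec.design()
    n_c, n_s, n_r = len(spec.cultivars), len(spec.stages), spec.reps
    n_samples = n_c * n_s * n_r
    genes = pd.Index([f"G{i:05d}" for i in range(spec.n_genes)], name="gene")

    archetype = _allocate_archetypes(spec)
    m = rng_expr.normal(spec.gene_mean_loc, spec.gene_mean_scale, spec.n_genes)
    beta = rng_expr.normal(0.0, spec.baseline_sd, spec.n_genes)
    amplitude = rng_expr.uniform(*spec.amplitude_range, spec.n_genes)
    jitter = rng_expr.normal(0.0, spec.cultivar_jitter_sd, (spec.n_genes, n_c))

    t_c = _cultivar_scores(spec.cultivars)
    high = np.array([g == "High" for _, g in spec.cultivars])

    # planted divergence window per gene (zeros when not divergent)
    window = np.zeros((spec.n_genes, n_s))
    u = np.zeros(spec.n_genes)
    peak_stage = np.full(spec.n_genes, "", dtype=object)
    for mod, pdiv in spec.divergent_modules.items():
        idx = np.flatnonzero(archetype == mod)
        u[idx] = rng_expr.uniform(*spec.divergence_gene_scale, idx.size)
        w = np.full(n_s, pdiv.off_offset)
        w[spec.stages.index(pdiv.peak_stage)] = pdiv.peak_offset
        window[idx] = u[idx, None] * w[None, :]
        peak_stage[idx] = pdiv.peak_stage

    # replicate-centred latent factors for the planted co-expression blocks
    loading = np.zeros(spec.n_genes)
    block = np.full(spec.n_genes, -1)
    factors = np.zeros((len(spec.coexpr_blocks), n_c, n_s, n_r))
    for bi, b in enumerate(spec.coexpr_blocks):
        idx = np.flatnonzero(archetype == b)
        loading[idx] = rng_expr.uniform(*spec.coexpr_loading, idx.size)
        block[idx] = b
        f = rng_expr.normal(0.0, 1.0, (n_c, n_s, n_r))
        factors[bi] = f - f.mean(axis=2, keepdims=True)

    x = np.empty((spec.n_genes, n_samples))
    col = 0
    for ci in range(n_c):
        for si in range(n_s):
            for ri in range(n_r):
                val = (m + beta * t_c[ci] + jitter[:, ci]
                       + amplitude * spec.archetypes[archetype, si])
                if high[ci]:
                    val = val + window[:, si]
                for bi, b in enumerate(spec.coexpr_blocks):
                    sel = block == b
                    val = val.copy()
                    val[sel] += loading[sel] * factors[bi, ci, si, ri]
                x[:, col] = val
                col += 1
    if spec.noise_sd > 0:
        x = x + rng_expr.normal(0.0, spec.noise_sd, x.shape)

    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=list(design["sample_id"])), design)

    classes = rng_ann.choice(list(spec.class_probs), size=spec.n_genes,
                             p=list(spec.class_probs.values()))
    truth = pd.DataFrame(
        {
            "archetype": archetype,
            "amplitude": amplitude,
            "divergent": u > 0,
            "divergence_scale": u,
            "peak_stage": peak_stage,
            "coexpr_block": block,
            "loading": loading,
            "class": classes,
        },
        index=genes,
    )

    hormones = generate_hormones(expr, truth, spec, rng=rng_horm)
    annotations = generate_annotations(truth, rng=rng_ann,
                                       class_series=pd.Series(classes, index=genes))
    return SyntheticDataset(expr, hormones, annotations, truth, spec,
                            aba_coupling=spec.aba_coupling)


def _ga_stage_means(spec: TruthSpec) -> tuple[np.ndarray, np.ndarray]:
    n_s = len(spec.stages)
    ga7 = 2.0 + np.arange(n_s, dtype=float)
    ga7[-1] = ga7[-2] * 2.5 + 2.0          # marked rise at the release stage
    ga3 = 5.0 + np.resize([0.0, -1.5, 1.0], n_s)
    return ga3, ga7


def generate_hormones(expression: ExpressionMatrix, truth: pd.DataFrame,
                      spec: TruthSpec,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate ABA/GA3/GA7 (ng/g) coupled to the planted hormone module.

    ABA per sample is ``aba_coupling * mean log2(TPM+1) of the hormone-module
    genes`` plus Normal noise; with the default S2-peaking archetype this
    reproduces the rise-then-fall ABA trajectory.  GA7 increases monotonically
    with a marked jump at the last stage; GA3 varies by stage.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[1])
    module_genes = truth.index[truth["archetype"] == spec.hormone_module]
    if len(module_genes) == 0:
        raise ValueError(f"hormone module {spec.hormone_module} has no genes")
    design = expression.design
    logx = np.log2(expression.values.loc[module_genes] + 1.0)
    module_mean = logx.mean(axis=0)

    aba = spec.aba_coupling * module_mean.to_numpy()
    if spec.aba_noise_sd > 0:
        aba = aba + rng.normal(0.0, spec.aba_noise_sd, aba.size)
    ga3_means, ga7_means = _ga_stage_means(spec)
    stage_idx = design["stage"].cat.codes.to_numpy()
    ga3 = ga3_means[stage_idx]
    ga7 = ga7_means[stage_idx]
    if spec.ga_noise_sd > 0:
        ga3 = ga3 + rng.normal(0.0, spec.ga_noise_sd, ga3.size)
        ga7 = ga7 + rng.normal(0.0, spec.ga_noise_sd, ga7.size)

    rows = []
    for name, vals in (("ABA", aba), ("GA3", ga3), ("GA7", ga7)):
        rows.append(pd.DataFrame({
            "sample_id": design["sample_id"],
            "hormone": name,
            "value": np.clip(vals, 0.01, None),
        }))
    return validate_hormones(pd.concat(rows, ignore_index=True), design)


def generate_annotations(truth: pd.DataFrame, term_size: int | None = None,
                         background_terms: int = 4,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         class_series: pd.Series | None = None) -> AnnotationTable:
    """One planted-enriched term per archetype plus random background terms.

    Each planted term covers ``term_size`` genes drawn from its archetype
    (default: 80% of the archetype, at least 1); background terms of the same
    size are assigned uniformly at random over the whole gene universe.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    genes = truth.index
    rows = []
    descriptions: dict[str, str] = {}
    for a in sorted(truth["archetype"].unique()):
        members = truth.index[truth["archetype"] == a]
        size = term_size if term_size is not None else max(1, int(0.8 * len(members)))
        if size > len(members):
            raise ValueError(
                f"term_size {size} exceeds archetype {a} size {len(members)}")
        chosen = rng.choice(members, size=size, replace=False)
        term = f"M{a}_PLANTED"
        descriptions[term] = f"planted term for trajectory archetype {a}"
        rows.append(pd.DataFrame({"gene": sorted(chosen), "term": term,
                                  "layer": "SIM"}))
        bg_size = size
    for j in range(background_terms):
        chosen = rng.choice(genes, size=min(bg_size, len(genes)), replace=False)
        term = f"BG{j}_RANDOM"
        descriptions[term] = "background term assigned uniformly at random"
        rows.append(pd.DataFrame({"gene": sorted(chosen), "term": term,
                                  "layer": "SIM"}))
    if class_series is None:
        class_series = truth["class"] if "class" in truth else pd.Series(dtype=object)
    return AnnotationTable(pd.concat(rows, ignore_index=True),
                           term_descriptions=descriptions,
                           classes=pd.Series(class_series, index=genes))


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the same TSV formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "hormones": outdir / "hormones.tsv",
        "annotations": outdir / "annotations.tsv",
        "classes": outdir / "classes.tsv",
        "truth": outdir / "truth_genes.tsv",
    }
    write_expression(ds.expression, paths["expression"])
    write_tsv(ds.expression.design, paths["samples"])
    write_tsv(ds.hormones, paths["hormones"])
    write_annotation_table(ds.annotations, paths["annotations"], paths["classes"])
    truth = ds.truth.rename_axis("gene").reset_index()
    write_tsv(truth, paths["truth"])
    return paths
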