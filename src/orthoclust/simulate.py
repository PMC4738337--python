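"""Two-species synthetic expression data with planted structure.

The generator emulates the statistical shape of a cross-species tumour
transcriptome study on the log2 scale:

* per species, K tumour subgroups of equal size, each defined by a program
  of m marker genes shifted by ±δ in that group only; each tumour sample
  expresses its program at a random strength (uniform around 1, emulating
  tumour purity), so group means shift by exactly ±δ in expectation while
  under-clustered partitions stay visibly ambiguous under resampling;
* a 1:1 ortholog core linking the two species; designated ("linked") group
  pairs share a program through the core, with an agreement fraction ρ of
  markers keeping their sign across species and the rest flipping it — so
  the expected cross-species agreement grows monotonically with ρ and is
  near zero at ρ = 0.5;
* a baseline-only reference tissue per species (the "cortex" used for
  differential vectors) and, optionally, one progenitor-like reference
  tissue per group carrying the same program (the planted cell-of-origin
  signal for centroid correlation);
* background genes (always below the 1.2 expression threshold) and
  invariant genes (tight spread, RIQR below 0.75) so both gene filters have
  work to do — by construction these fail their filters deterministically.

Marker genes draw their off-state baseline from a low-expression regime
(defaults: mean 0.7, sd 0.15) while non-marker expressed genes sit around a
mean of 6.0: subgroup markers in real arrays are near-silent outside their
subgroup, and a *relative* IQR threshold of 0.75 can only be cleared by
genes whose spread is large compared to their own median. Down-shifted
markers can dip slightly below zero; values are left unclipped (the
clustering NMF stage clips explicitly instead), keeping planted group-mean
differences exactly at δ.

The default is K = 3 subgroups per species. Quartile-based spread
statistics are blind to genes that deviate in fewer than 25% of samples,
so a marker exclusive to one of K equal groups can only register when
K <= 3; with K = 3 each group holds a third of the tumour cohort and its
markers clear the variability filter with margin.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthologMap


@dataclass
class SimulationParams:
    """Knobs of the two-species generator (log2 units throughout)."""

    n_genes: int = 800              # regular (expressed) genes per species
    ortholog_core: int = 250        # first genes of each species, 1:1 paired
    background_genes: int = 100
    invariant_genes: int = 100
    k_a: int = 3                    # tumour subgroups, species A
    k_b: int = 3                    # tumour subgroups, species B
    samples_per_group: int = 5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    marker_baseline_mean: float = 0.7
    marker_baseline_sd: float = 0.15
    program_size: int = 40          # marker genes per group
    effect_size: float = 2.0        # δ
    agreement: float = 0.8          # ρ, sign-concordant fraction for linked pairs
    noise_sd: float = 0.5           # σ
    purity_range: tuple = (0.4, 1.6)  # per-tumour program-strength jitter, mean 1
    mixing_max: float = 0.25        # max strength of a secondary group program
    sharing: tuple = ((0, 1), (1, 2))   # (A-group index, B-group index) pairs
    cortex_samples: int = 8
    progenitor_samples: int = 4
    progenitor_references: bool = True
    species_a: str = "mouse"
    species_b: str = "human"
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "k_a", "k_b", "samples_per_group",
                     "program_size", "cortex_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.agreement <= 1:
            raise ValueError("agreement must lie in [0, 1]")
        if self.ortholog_core > self.n_genes:
            raise ValueError("ortholog_core cannot exceed n_genes")
        n_linked = len(self.sharing)
        if n_linked * self.program_size > self.ortholog_core:
            raise ValueError("linked programs exceed the ortholog core")
        for a_idx, b_idx, *rest in self.sharing:
            if not (0 <= a_idx < self.k_a and 0 <= b_idx < self.k_b):
                raise ValueError(f"sharing pair ({a_idx}, {b_idx}) out of range")
        free = self.n_genes - self.ortholog_core
        if (self.k_a - n_linked) * self.program_size > free:
            raise ValueError("species-A non-core programs exceed available genes")
        if (self.k_b - n_linked) * self.program_size > free:
            raise ValueError("species-B non-core programs exceed available genes")


@dataclass
class SyntheticTruth:
    """Ground truth written alongside every simulated dataset."""

    labels: dict                    # species -> {sample_id: group}
    programs: dict                  # (species, group) -> {gene_id: sign}
    sharing: list                   # [{group_a, group_b, rho}]
    reference_samples: dict         # species -> {reference name: [sample ids]}
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    ortholog_map: OrthologMap
    annotation: pd.DataFrame
    truth: SyntheticTruth


def _gene_ids(species: str, params: SimulationParams):
    p = species[0]
    total = params.n_genes + params.background_genes + params.invariant_genes
    return [f"{p}g{i:05d}" for i in range(total)]


def _species_matrix(
    species: str,
    k: int,
    programs_idx: dict,
    signs: dict,
    params: SimulationParams,
    rng,
):
    """Build one species' matrix, annotation rows, and truth pieces."""
    genes = _gene_ids(species, params)
    n_reg, n_bg, n_inv = params.n_genes, params.background_genes, params.invariant_genes
    marker = np.zeros(n_reg, dtype=bool)
    for idx in programs_idx.values():
        marker[idx] = True
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n_reg)
    baseline[marker] = rng.normal(
        params.marker_baseline_mean, params.marker_baseline_sd, size=int(marker.sum())
    )
    inv_baseline = np.clip(
        rng.normal(params.baseline_mean, params.baseline_sd, size=n_inv), 2.0, None
    )

    groups = [f"{species}_g{i + 1}" for i in range(k)]
    columns, ann_rows = [], []
    effects = []  # per sample: dict gene_index -> shift on regular genes
    labels = {}
    ref_samples: dict = {}
    lo, hi = params.purity_range
    if not 0 <= lo <= hi:
        raise ValueError("purity_range must satisfy 0 <= lo <= hi")
    if params.mixing_max < 0:
        raise ValueError("mixing_max must be >= 0")
    for gi, gname in enumerate(groups):
        for j in range(params.samples_per_group):
            sid = f"{gname}_s{j + 1}"
            columns.append(sid)
            ann_rows.append((sid, species, gname, "tumour"))
            # tumour purity / program-strength jitter, E[strength] = 1
            idx = programs_idx[gi]
            sg = signs[gi] * rng.uniform(lo, hi)
            if k > 1 and params.mixing_max > 0:
                # weak secondary program: shared differentiation states make
                # under-clustered partitions ambiguous, as in real cohorts
                other = int(rng.choice([h for h in range(k) if h != gi]))
                w = rng.uniform(0.0, params.mixing_max)
                idx = np.concatenate([idx, programs_idx[other]])
                sg = np.concatenate([sg, signs[other] * w])
            effects.append((idx, sg))
            labels[sid] = gname
    cortex = f"{species}_cortex"
    ref_samples[cortex] = []
    for j in range(params.cortex_samples):
        sid = f"{cortex}_s{j + 1}"
        columns.append(sid)
        ann_rows.append((sid, species, cortex, "reference"))
        effects.append((np.array([], dtype=int), np.array([])))
        ref_samples[cortex].append(sid)
    if params.progenitor_references:
        for gi in range(k):
            pname = f"{species}_prog{gi + 1}"
            ref_samples[pname] = []
            for j in range(params.progenitor_samples):
                sid = f"{pname}_s{j + 1}"
                columns.append(sid)
                ann_rows.append((sid, species, pname, "reference"))
                effects.append((programs_idx[gi], signs[gi]))
                ref_samples[pname].append(sid)

    n_samples = len(columns)
    X = np.empty((n_reg + n_bg + n_inv, n_samples))
    reg = baseline[:, None] + rng.normal(0.0, params.noise_sd, size=(n_reg, n_samples))
    for s, (idx, sg) in enumerate(effects):
        if len(idx):
            reg[idx, s] += sg * params.effect_size
    X[:n_reg] = reg
    # background genes: strictly below the 1.2 expression threshold
    X[n_reg:n_reg + n_bg] = rng.uniform(0.0, 1.15, size=(n_bg, n_samples))
    # invariant genes: expressed but with near-zero spread
    X[n_reg + n_bg:] = inv_baseline[:, None] + rng.uniform(
        -0.01, 0.01, size=(n_inv, n_samples)
    )
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=columns), species)
    programs = {
        (species, groups[gi]): {
            genes[g]: int(s) for g, s in zip(programs_idx[gi], signs[gi])
        }
        for gi in range(k)
    }
    return expr, ann_rows, labels, programs, ref_samples, groups


def generate(params: SimulationParams | None = None, **overrides) -> SyntheticDataset:
    """Generate the full two-species dataset with ground truth.

    Keyword overrides are applied on top of ``params`` (or the defaults).
    """
    if params is None:
        params = SimulationParams()
    if overrides:
        params = SimulationParams(**{**asdict(params), **overrides})
    params.validate()
    rng = np.random.default_rng(params.seed)
    m = params.program_size

    sharing = [tuple(s) for s in params.sharing]
    linked_a = {s[0] for s in sharing}
    linked_b = {s[1] for s in sharing}
    if len(linked_a) != len(sharing) or len(linked_b) != len(sharing):
        raise ValueError("sharing must pair each group at most once")

    # allocate program gene indices: linked pairs in the ortholog core
    # (same core index on both sides), the rest outside it
    prog_a: dict = {}
    prog_b: dict = {}
    signs_a: dict = {}
    signs_b: dict = {}
    core_cursor = 0
    for entry in sharing:
        a_idx, b_idx = entry[0], entry[1]
        rho = entry[2] if len(entry) > 2 else params.agreement
        idx = np.arange(core_cursor, core_cursor + m)
        core_cursor += m
        prog_a[a_idx] = idx
        prog_b[b_idx] = idx.copy()
        sa = rng.choice([-1.0, 1.0], size=m)
        n_agree = int(round(rho * m))
        sb = sa.copy()
        sb[n_agree:] *= -1.0  # disagreeing markers flip sign across species
        signs_a[a_idx] = sa
        signs_b[b_idx] = sb
    cursor_a = cursor_b = params.ortholog_core
    for gi in range(params.k_a):
        if gi not in prog_a:
            prog_a[gi] = np.arange(cursor_a, cursor_a + m)
            cursor_a += m
            signs_a[gi] = rng.choice([-1.0, 1.0], size=m)
    for gi in range(params.k_b):
        if gi not in prog_b:
            prog_b[gi] = np.arange(cursor_b, cursor_b + m)
            cursor_b += m
            signs_b[gi] = rng.choice([-1.0, 1.0], size=m)

    expr_a, rows_a, labels_a, programs_a, refs_a, groups_a = _species_matrix(
        params.species_a, params.k_a, prog_a, signs_a, params, rng
    )
    expr_b, rows_b, labels_b, programs_b, refs_b, groups_b = _species_matrix(
        params.species_b, params.k_b, prog_b, signs_b, params, rng
    )

    genes_a = _gene_ids(params.species_a, params)
    genes_b = _gene_ids(params.species_b, params)
    pairs = pd.DataFrame(
        {
            "gene_a": genes_a[: params.ortholog_core],
            "gene_b": genes_b[: params.ortholog_core],
        }
    )
    omap = OrthologMap(pairs, provenance="synthetic 1:1 core")

    annotation = pd.DataFrame(
        rows_a + rows_b, columns=["sample_id", "species", "group", "role"]
    )
    truth = SyntheticTruth(
        labels={params.species_a: labels_a, params.species_b: labels_b},
        programs={**programs_a, **programs_b},
        sharing=[
            {
                "group_a": groups_a[s[0]],
                "group_b": groups_b[s[1]],
                "rho": (s[2] if len(s) > 2 else params.agreement),
            }
            for s in sharing
        ],
        reference_samples={params.species_a: refs_a, params.species_b: refs_b},
        params=asdict(params),
    )
    return SyntheticDataset(expr_a, expr_b, omap, annotation, truth)


def generate_null(
    n_genes: int = 1000,
    samples_per_group: int = 5,
    n_groups: int = 2,
    noise_sd: float = 0.5,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.5,
    species: str = "null",
    seed: int = 0,
):
    """Pure-noise dataset (no group structure) for type-I-error and FDR checks."""
    if min(n_genes, samples_per_group, n_groups) <= 0:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    n = samples_per_group * n_groups
    X = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n))
    genes = [f"ng{i:05d}" for i in range(n_genes)]
    columns, rows = [], []
    for gi in range(n_groups):
        for j in range(samples_per_group):
            sid = f"{species}_g{gi + 1}_s{j + 1}"
            columns.append(sid)
            rows.append((sid, species, f"{species}_g{gi + 1}", "tumour"))
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=columns), species)
    ann = pd.DataFrame(rows, columns=["sample_id", "species", "group", "role"])
    return expr, ann
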