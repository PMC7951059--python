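"""Synthetic cohort generation with known ground truth.

Emulates the inputs of the MYCN immune-landscape pipeline: a two-group
(MNA vs non-MNA) log-normal bulk expression cohort with planted
group-associated genes, planted proportional-hazards survival structure and
planted co-expression factors; cell-type reference profiles with known
mixing fractions; a protein annotation / interaction fixture for the
surface-protein network; and a TF->target prior aligned with the planted
modules.  Every generator returns the truth it planted so downstream
recovery can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_reference_and_mixtures",
    "generate_interactome_fixture",
    "generate_tf_prior",
]

# surface-location vocabulary shared with the network stage
SURFACE_TERMS = ("plasma membrane", "cell junctions", "focal adhesion sites")
RELIABLE_STATUSES = ("approved", "supported")


@dataclass
class CohortConfig:
    """Parameters of a simulated two-group expression cohort.

    Expression is on the log2 scale: ``baseline + group effect + factor
    structure + N(0, noise_sd)``.  Survival times follow an exponential
    proportional-hazards model on the centred planted-gene linear
    predictor, with independent exponential censoring.
    """

    n_samples: int = 600
    mna_fraction: float = 0.2
    n_genes: int = 2000
    n_pos_genes: int = 60          # up in the MNA group
    pos_effect: float = 1.5        # log2 units added in MNA samples
    n_neg_genes: int = 40          # up in the non-MNA group
    neg_effect: float = 1.5
    hazard_pos: float = 0.8        # log-hazard coefficient of each pos gene
    hazard_neg: float = -0.8
    hazard_betas: Mapping[str, float] | None = None  # overrides the defaults
    standardize_lp: bool = True    # centre/unit-scale the linear predictor
    baseline_hazard: float = 0.1   # events per time unit
    censor_rate: float = 0.05
    module_spec: Sequence[tuple[int, float]] = ()    # (size, factor loading)
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0.0 < self.mna_fraction < 1.0:
            raise ValueError("mna_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_pos_genes < 0 or self.n_neg_genes < 0:
            raise ValueError("planted gene counts must be >= 0")
        n_module = sum(s for s, _ in self.module_spec)
        if self.n_pos_genes + self.n_neg_genes + n_module > self.n_genes:
            raise ValueError(
                "planted genes (%d signature + %d module) exceed n_genes=%d"
                % (self.n_pos_genes + self.n_neg_genes, n_module, self.n_genes)
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator planted, for recovery tests."""

    pos_signature: dict[str, float] = field(default_factory=dict)
    neg_signature: dict[str, float] = field(default_factory=dict)
    hazard_coefficients: dict[str, float] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    module_factors: pd.DataFrame | None = None      # module x sample latent factors
    linear_predictor: pd.Series | None = None       # per-sample true log-hazard
    true_fractions: pd.DataFrame | None = None
    true_regulons: dict[str, set[str]] = field(default_factory=dict)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: CohortConfig) -> tuple[dict, GroundTruth]:
    """Simulate a two-group log2 expression cohort with survival.

    Returns ``(cohort, truth)`` where ``cohort`` has keys ``expression``
    (genes x samples DataFrame, log2 scale) and ``clinical`` (per-sample
    DataFrame with ``mna_status``, ``surv_time``, ``surv_event``,
    ``stage``).
    """
    config.validate()
    rng_group, rng_base, rng_fac, rng_noise, rng_surv, rng_stage = _streams(config.seed, 6)

    n, g = config.n_samples, config.n_genes
    genes = [f"G{i:04d}" for i in range(g)]
    samples = [f"S{i:04d}" for i in range(n)]

    n_mna = max(1, int(round(n * config.mna_fraction)))
    mna = np.zeros(n, dtype=int)
    mna[rng_group.choice(n, size=n_mna, replace=False)] = 1

    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, size=g)
    expr = np.tile(baseline[:, None], (1, n))

    # planted group effects: first n_pos genes up in MNA, next n_neg up in non-MNA
    pos_genes = genes[: config.n_pos_genes]
    neg_genes = genes[config.n_pos_genes : config.n_pos_genes + config.n_neg_genes]
    expr[: config.n_pos_genes, mna == 1] += config.pos_effect
    expr[config.n_pos_genes : config.n_pos_genes + config.n_neg_genes, mna == 0] += config.neg_effect

    # planted co-expression factors on the genes after the signature block
    truth = GroundTruth(
        pos_signature={gn: config.pos_effect for gn in pos_genes},
        neg_signature={gn: config.neg_effect for gn in neg_genes},
    )
    offset = config.n_pos_genes + config.n_neg_genes
    factors = {}
    for m, (size, loading) in enumerate(config.module_spec, start=1):
        f = rng_fac.normal(size=n)
        factors[m] = f
        expr[offset : offset + size] += loading * f[None, :]
        for gn in genes[offset : offset + size]:
            truth.module_labels[gn] = m
        offset += size
    if factors:
        truth.module_factors = pd.DataFrame(factors, index=samples).T

    if config.noise_sd > 0:
        expr += rng_noise.normal(0.0, config.noise_sd, size=expr.shape)

    expression = pd.DataFrame(expr, index=genes, columns=samples)

    # survival: exponential PH on the centred planted linear predictor
    betas: dict[str, float] = {}
    if config.hazard_betas is not None:
        betas = dict(config.hazard_betas)
    else:
        betas.update({gn: config.hazard_pos for gn in pos_genes})
        betas.update({gn: config.hazard_neg for gn in neg_genes})
    truth.hazard_coefficients = betas

    lp = np.zeros(n)
    for gn, b in betas.items():
        x = expression.loc[gn].to_numpy()
        lp += b * (x - x.mean())
    if config.standardize_lp and lp.std() > 0:
        lp = lp / lp.std()
    truth.linear_predictor = pd.Series(lp, index=samples)

    t_event = rng_surv.exponential(1.0 / (config.baseline_hazard * np.exp(lp)))
    if config.censor_rate > 0:
        t_cens = rng_surv.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    surv_time = np.minimum(t_event, t_cens)
    surv_event = (t_event <= t_cens).astype(int)

    # stage: MNA tumours enriched for stage 4
    stage = np.where(
        mna == 1,
        rng_stage.choice([3, 4], size=n, p=[0.3, 0.7]),
        rng_stage.choice([1, 2, 3, 4], size=n),
    )
    clinical = pd.DataFrame(
        {
            "mna_status": mna,
            "surv_time": surv_time,
            "surv_event": surv_event,
            "stage": stage,
        },
        index=samples,
    )
    return {"expression": expression, "clinical": clinical}, truth


@dataclass
class MixtureConfig:
    """Parameters of the reference-profile / mixture simulation (linear scale)."""

    n_types: int = 5
    markers_per_type: int = 40
    n_background_genes: int = 100
    n_refs_per_type: int = 3
    n_mixtures: int = 40
    marker_level: float = 500.0    # linear expression of a marker in its own type
    base_level: float = 20.0       # linear expression elsewhere
    noise_sd: float = 0.05         # multiplicative: sd = noise_sd * value
    seed: int = 0


def generate_reference_and_mixtures(
    config: MixtureConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Simulate reference profiles and bulk mixtures with known fractions.

    Returns ``(refs, type_map, mixtures, true_fractions)``: a genes x
    reference-sample matrix (linear scale), the reference-sample ->
    cell-type map, a genes x mixture matrix with
    ``mixture = fractions @ reference + noise`` and the samples x types
    fraction matrix (rows on the uniform simplex).
    """
    if config.n_types < 2:
        raise ValueError("at least 2 cell types are required")
    if config.markers_per_type < 1:
        raise ValueError("each cell type needs at least one marker gene")
    rng_ref, rng_frac, rng_noise = _streams(config.seed, 3)

    types = [f"T{t}" for t in range(config.n_types)]
    n_marker = config.n_types * config.markers_per_type
    genes = [f"M{i:04d}" for i in range(n_marker)] + [
        f"B{i:04d}" for i in range(config.n_background_genes)
    ]

    # true per-type mean profile: marker block high in own type
    profile = np.full((len(genes), config.n_types), config.base_level)
    for t in range(config.n_types):
        lo = t * config.markers_per_type
        profile[lo : lo + config.markers_per_type, t] = config.marker_level
    # background genes vary by type a little so the matrix is full rank
    profile[n_marker:] *= 1.0 + 0.1 * rng_ref.standard_normal(
        (config.n_background_genes, config.n_types)
    )
    profile = np.clip(profile, 0.0, None)

    ref_cols, ref_types = [], []
    ref_vals = []
    for t, tname in enumerate(types):
        for r in range(config.n_refs_per_type):
            ref_cols.append(f"{tname}_ref{r}")
            ref_types.append(tname)
            noise = 1.0 + config.noise_sd * rng_ref.standard_normal(len(genes))
            ref_vals.append(np.clip(profile[:, t] * noise, 0.0, None))
    refs = pd.DataFrame(np.column_stack(ref_vals), index=genes, columns=ref_cols)
    type_map = pd.Series(ref_types, index=ref_cols, name="cell_type")

    fractions = rng_frac.dirichlet(np.ones(config.n_types), size=config.n_mixtures)
    mix = profile @ fractions.T
    if config.noise_sd > 0:
        mix = mix * (1.0 + config.noise_sd * rng_noise.standard_normal(mix.shape))
    mix = np.clip(mix, 0.0, None)
    samples = [f"X{i:03d}" for i in range(config.n_mixtures)]
    mixtures = pd.DataFrame(mix, index=genes, columns=samples)
    true_fractions = pd.DataFrame(fractions, index=samples, columns=types)
    return refs, type_map, mixtures, true_fractions


def generate_interactome_fixture(seed: int = 0, n_extra_edges: int = 30):
    """Emit an annotation table, an edge table and the expected network.

    The fixture plants proteins whose locations, reliability statuses,
    per-population scores and interaction scores straddle every filter
    boundary of the surface-protein network cascade (reliable surface
    location; population score > 1.5; interaction score > 400).  The
    expected network is derived here by directly applying each filter,
    independent of the pipeline implementation.
    """
    from .io import AnnotationTable  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    populations = ["NK", "CD8T", "Bcell"]

    tumor_genes = [f"TUM{i}" for i in range(8)]
    imm = [f"IMM{i}" for i in range(10)]

    loc_rows = []
    # tumor genes: all reliable surface
    for p in tumor_genes:
        loc_rows.append((p, "plasma membrane", "approved"))
    # immune proteins with varied locations/statuses around the boundaries
    loc_rows += [
        (imm[0], "plasma membrane", "approved"),
        (imm[1], "cell junctions", "supported"),
        (imm[2], "focal adhesion sites", "approved"),
        (imm[3], "cytosol", "approved"),                # never surface
        (imm[4], "plasma membrane", "uncertain"),       # unreliable status
        (imm[5], "plasma membrane", "approved"),
        (imm[6], "nucleus", "supported"),
        (imm[6], "plasma membrane", "supported"),
        (imm[7], "plasma membrane", "approved"),
        (imm[8], "plasma membrane", "supported"),
        (imm[9], "cytosol", "supported"),
    ]
    locations = pd.DataFrame(loc_rows, columns=["protein", "location", "status"])

    # per-population scores straddling 1.5 (1.5 exactly must be excluded)
    proteins = tumor_genes + imm
    scores = pd.DataFrame(
        rng.uniform(0.0, 1.4, size=(len(proteins), len(populations))),
        index=proteins,
        columns=populations,
    )
    scores.loc[imm[0], "NK"] = 2.0
    scores.loc[imm[1], "NK"] = 1.51
    scores.loc[imm[1], "CD8T"] = 3.0
    scores.loc[imm[2], "Bcell"] = 1.5      # boundary: excluded
    scores.loc[imm[2], "CD8T"] = 1.6
    scores.loc[imm[3], "NK"] = 3.0         # high score but not surface
    scores.loc[imm[4], "NK"] = 3.0         # surface term not reliable
    scores.loc[imm[5], "Bcell"] = 2.5
    scores.loc[imm[6], "CD8T"] = 1.7
    scores.loc[imm[7], "NK"] = 1.5         # boundary: excluded
    scores.loc[imm[8], "NK"] = 1.9
    annotation = AnnotationTable(locations=locations, scores=scores)

    # edges straddling 400 (400 exactly excluded), plus a self-loop and decoys
    edge_rows = [
        (tumor_genes[0], imm[0], 900),
        (tumor_genes[0], imm[1], 401),
        (tumor_genes[1], imm[1], 400),     # boundary: excluded
        (tumor_genes[1], imm[2], 700),
        (tumor_genes[2], imm[3], 950),     # immune side not surface
        (tumor_genes[2], imm[4], 950),     # immune side unreliable
        (tumor_genes[3], imm[5], 500),
        (tumor_genes[3], imm[6], 399),     # below threshold
        (tumor_genes[4], imm[6], 800),
        (tumor_genes[4], imm[7], 990),     # score 1.5 exactly: no population
        (tumor_genes[5], imm[8], 450),
        (tumor_genes[5], tumor_genes[5], 999),  # self loop
        (imm[0], tumor_genes[6], 600),     # reversed orientation
    ]
    for _ in range(n_extra_edges):
        a, b = rng.choice(proteins, size=2, replace=False)
        edge_rows.append((a, b, int(rng.integers(0, 1001))))
    edges = pd.DataFrame(edge_rows, columns=["protein1", "protein2", "combined_score"])

    # brute-force expected network
    surface = {
        p
        for p, term, status in locations.itertuples(index=False)
        if term in SURFACE_TERMS and status in RELIABLE_STATUSES
    }
    pop_sets = {
        pop: {p for p in proteins if p in surface and scores.loc[p, pop] > 1.5}
        for pop in populations
    }
    tumor_set = set(tumor_genes)
    expected = set()
    best: dict[frozenset, int] = {}     # undirected dedup keeps the max score
    for a, b, s in edges.itertuples(index=False):
        if a == b:
            continue
        pair = frozenset((a, b))
        best[pair] = max(best.get(pair, 0), s)
    for pair, s in best.items():
        if s <= 400:
            continue
        a, b = sorted(pair)
        for pop, members in pop_sets.items():
            if a in tumor_set and b in members:
                expected.add((a, b, pop))
            if b in tumor_set and a in members:
                expected.add((b, a, pop))
    return annotation, edges, expected


def generate_tf_prior(
    truth: GroundTruth,
    targets_per_tf: int = 40,
    purity: float = 0.9,
    n_decoys: int = 5,
    universe: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Build a TF -> target prior aligned with the planted modules.

    One TF per planted module draws ``purity`` of its targets from that
    module (the rest uniformly from the universe); ``n_decoys`` decoy TFs
    draw all targets uniformly.  Requires a cohort generated with a
    non-empty ``module_spec``.
    """
    if not truth.module_labels:
        raise ValueError("no modules configured: generate the cohort with module_spec")
    rng = np.random.default_rng(seed)
    modules: dict[int, list[str]] = {}
    for gene, m in truth.module_labels.items():
        modules.setdefault(m, []).append(gene)
    if universe is None:
        universe = sorted(truth.module_labels)
    universe = list(universe)

    prior: dict[str, set[str]] = {}
    for m in sorted(modules):
        member = modules[m]
        n_in = min(len(member), int(round(purity * targets_per_tf)))
        chosen = set(rng.choice(member, size=n_in, replace=False))
        outside = [g for g in universe if g not in chosen]
        n_out = min(targets_per_tf - n_in, len(outside))
        if n_out > 0:
            chosen |= set(rng.choice(outside, size=n_out, replace=False))
        prior[f"TF_M{m}"] = chosen
    for d in range(n_decoys):
        prior[f"TF_DECOY{d}"] = set(
            rng.choice(universe, size=min(targets_per_tf, len(universe)), replace=False)
        )
    truth.true_regulons = {tf: set(t) for tf, t in prior.items() if not tf.startswith("TF_DECOY")}
    return prior
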