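"""Synthetic cohort generator for layer-resolved arterial ROI profiling.

Emulates the design of a GeoMx-style temporal-artery study: case and control
patients, one or more ROIs per patient in each arterial layer (intima, media,
adventitia, PVAT), negative-probe background, log-normal library-size
variation, patient-level random intercepts and layer-graded differential
expression, with case layers predominantly upregulated.

Counts follow a negative binomial with a log link:

    count(g, roi) ~ NB(mean = 2^(b_g + u_p + delta_{g,layer,status}) * s_roi,
                       size = nb_dispersion)

where ``b_g`` is the gene's baseline log2 mean, ``u_p`` the patient random
intercept (log2 scale), ``delta`` the planted log2 fold change (case ROIs of
the affected layer only) and ``s_roi`` a log-normal ROI size factor. Negative
probes and background-only targets are drawn from the same background law
(no patient effect, no DE), making them exchangeable in distribution.

Companion generators emit gene sets (GMT), a scored interaction edge table
and a drug-gene table with planted structure so enrichment and network
stages have known positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError

DEFAULT_LAYERS = ("intima", "media", "adventitia", "PVAT")

# Layer-graded DE burden mirroring the intima > media > adventitia > PVAT
# gradient of the arterial disease process, scaled to desk size.
DEFAULT_DE_SPEC: Dict[str, List[Tuple[int, float]]] = {
    "intima": [(280, 2.0)],
    "media": [(225, 2.0)],
    "adventitia": [(40, 2.0)],
    "PVAT": [(5, 2.0)],
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design at desk scale: 9 case / 7 control
    patients, 4 layers, one ROI per patient-layer, ~2,000 targets with 139
    negative probes, patient random intercepts of SD 0.5 (log2) and a
    predominantly upregulated, layer-graded DE burden.
    """

    n_case_patients: int = 9
    n_control_patients: int = 7
    layers: Tuple[str, ...] = DEFAULT_LAYERS
    rois_per_patient_layer: int = 1
    n_targets: int = 2000
    n_neg_probes: int = 139
    baseline_log2_mean_range: Tuple[float, float] = (3.0, 9.0)
    background_log2_mean: float = 1.0
    nb_dispersion: float = 10.0
    patient_sd: float = 0.5
    libsize_sd: float = 0.3
    de_spec: Dict[str, List[Tuple[int, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DE_SPEC.items()}
    )
    up_fraction: float = 0.9
    undetectable_frac: float = 1.0 / 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case_patients", "n_control_patients", "rois_per_patient_layer",
                     "n_targets", "n_neg_probes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_case_patients + self.n_control_patients == 0:
            raise ValidationError("n_case_patients + n_control_patients must be > 0")
        if len(self.layers) == 0:
            raise ValidationError("layers must be non-empty")
        if len(set(self.layers)) != len(self.layers):
            raise ValidationError("layers must be unique")
        if self.n_neg_probes < 2:
            raise ValidationError("n_neg_probes must be >= 2 (geoSD needs two values)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.patient_sd < 0:
            raise ValidationError("patient_sd must be non-negative")
        if self.libsize_sd < 0:
            raise ValidationError("libsize_sd must be non-negative")
        if not 0.0 <= self.undetectable_frac <= 1.0:
            raise ValidationError("undetectable_frac must lie in [0, 1]")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValidationError("up_fraction must lie in [0, 1]")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise ValidationError("baseline_log2_mean_range must be a (lo, hi) interval")
        for layer, entries in self.de_spec.items():
            if layer not in self.layers:
                raise ValidationError(f"de_spec layer {layer!r} not among layers")
            total = sum(n for n, _ in entries)
            if total > self.n_targets:
                raise ValidationError(
                    f"de_spec for {layer!r} plants {total} genes > n_targets")


def full_scale_config(seed: int = 0) -> CohortConfig:
    """Panel-scale profile (~18,000 targets); not needed for routine tests."""
    return replace(CohortConfig(), n_targets=18000, seed=seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_cohort(config: CohortConfig) -> Tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate (CountMatrix, RoiMeta DataFrame, TruthTable DataFrame).

    The truth table is long-form with one row per (gene, layer):
    ``true_log2fc``, ``is_de`` and ``is_background_only``. Identical
    (config, seed) reproduces identical output bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_targets)]
    negprobes = [f"NegProbe{i:03d}" for i in range(config.n_neg_probes)]
    targets = genes + negprobes

    patients = (
        [f"GCA{i+1:02d}" for i in range(config.n_case_patients)]
        + [f"CTRL{i+1:02d}" for i in range(config.n_control_patients)]
    )
    statuses = ["GCA"] * config.n_case_patients + ["control"] * config.n_control_patients
    sexes = rng.choice(["F", "M"], size=len(patients))

    rows = []
    for patient, status, sex in zip(patients, statuses, sexes):
        for layer in config.layers:
            for k in range(config.rois_per_patient_layer):
                rows.append(
                    {"roi": f"{patient}_{layer}_{k+1}", "patient": patient,
                     "status": status, "layer": layer, "sex": sex}
                )
    meta = pd.DataFrame(rows).set_index("roi")

    # gene baselines; a fixed fraction sits at the background level
    n_bg = int(round(config.undetectable_frac * config.n_targets))
    bg_idx = rng.choice(config.n_targets, size=n_bg, replace=False)
    is_background = np.zeros(config.n_targets, dtype=bool)
    is_background[bg_idx] = True
    lo, hi = config.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_targets)
    baseline[is_background] = config.background_log2_mean

    # planted effects: per layer, DE genes drawn from expressed (non-background)
    # targets; sign up with probability up_fraction
    expressed_idx = np.flatnonzero(~is_background)
    lfc = {layer: np.zeros(config.n_targets) for layer in config.layers}
    for layer in config.layers:
        for n_de, magnitude in config.de_spec.get(layer, []):
            if n_de == 0 or magnitude == 0:
                continue
            if n_de > len(expressed_idx):
                raise ValidationError(
                    f"de_spec for {layer!r} plants {n_de} genes but only "
                    f"{len(expressed_idx)} non-background targets exist; "
                    "lower undetectable_frac or the de_spec counts")
            chosen = rng.choice(expressed_idx, size=n_de, replace=False)
            signs = np.where(rng.random(n_de) < config.up_fraction, 1.0, -1.0)
            lfc[layer][chosen] = signs * abs(magnitude)

    patient_effect = dict(zip(patients, rng.normal(0.0, config.patient_sd, len(patients))))
    size_factors = 2.0 ** rng.normal(0.0, config.libsize_sd, size=len(meta))

    counts = np.zeros((len(targets), len(meta)), dtype=np.int64)
    bg_mean = 2.0 ** config.background_log2_mean
    for j, (roi, row) in enumerate(meta.iterrows()):
        s = size_factors[j]
        log2_mu = baseline + patient_effect[row["patient"]]
        if row["status"] == "GCA":
            log2_mu = log2_mu + lfc[row["layer"]]
        mu = 2.0 ** log2_mu * s
        # background targets and negative probes share one law: no patient
        # effect, no DE — they are exchangeable by construction
        mu[is_background] = bg_mean * s
        mu_full = np.concatenate([mu, np.full(config.n_neg_probes, bg_mean * s)])
        counts[:, j] = _nb_draw(rng, mu_full, config.nb_dispersion)

    count_df = pd.DataFrame(counts, index=targets, columns=meta.index)
    flags = pd.Series([False] * len(genes) + [True] * len(negprobes), index=targets)
    matrix = CountMatrix(count_df, flags)

    truth_rows = []
    for layer in config.layers:
        layer_lfc = lfc[layer]
        for i, gene in enumerate(genes):
            truth_rows.append(
                {"target": gene, "layer": layer, "true_log2fc": layer_lfc[i],
                 "is_de": bool(layer_lfc[i] != 0.0),
                 "is_background_only": bool(is_background[i])}
            )
    truth = pd.DataFrame(truth_rows)
    return matrix, meta, truth


def de_genes_from_truth(truth: pd.DataFrame, layer: str | None = None) -> List[str]:
    """Targets planted as DE (in the given layer, or any layer if None)."""
    sub = truth if layer is None else truth[truth["layer"] == layer]
    return sorted(sub.loc[sub["is_de"], "target"].unique())


def generate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 20,
    set_size_range: Tuple[int, int] = (10, 40),
    enrichment_bias: float = 0.8,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Random gene sets, half of them deliberately enriched for true DE genes.

    With ``enrichment_bias`` b, each member of an enriched set is drawn from
    the DE pool with probability b (uniform from the rest otherwise); b = 0
    reduces every set to a uniform random draw.
    """
    if truth.empty:
        raise ValidationError("truth table is empty")
    if not 0.0 <= enrichment_bias <= 1.0:
        raise ValidationError("enrichment_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(truth["target"].unique()))
    de_pool = np.array(de_genes_from_truth(truth))
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValidationError("set sizes exceed the number of targets")

    sets: Dict[str, List[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        enriched = enrichment_bias > 0 and len(de_pool) > 0 and i < n_sets // 2
        if enriched:
            n_de = int(np.sum(rng.random(size) < enrichment_bias))
            n_de = min(n_de, len(de_pool), size)
            members = list(rng.choice(de_pool, size=n_de, replace=False))
            rest_pool = np.setdiff1d(universe, np.array(members, dtype=universe.dtype))
            members += list(rng.choice(rest_pool, size=size - n_de, replace=False))
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        sets[f"SET{i:03d}"] = sorted(members)
    return sets


def generate_edge_and_drug_tables(
    targets: Sequence[str],
    truth: pd.DataFrame,
    seed: int = 0,
    n_background_edges: int = 200,
    background_score_range: Tuple[float, float] = (0.15, 0.89),
    clique_size: int = 5,
    clique_score: float = 0.95,
    planted_drug: str = "PLANTEDMAB",
    n_random_drug_rows: int = 50,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Scored interaction edges plus a drug-gene table with planted structure.

    A clique of ``clique_size`` true-DE genes is planted at ``clique_score``
    (above the usual 0.900 confidence cut) and each of its members is given
    one approved drug, so the network stage has a known main component and a
    known druggable annotation. Background edges score below the cut.
    """
    if len(targets) == 0:
        raise ValidationError("targets must be non-empty")
    rng = np.random.default_rng(seed)
    targets = list(targets)
    de_pool = [g for g in de_genes_from_truth(truth) if g in set(targets)]

    edge_rows = []
    clique: List[str] = []
    if clique_size > 0 and len(de_pool) >= clique_size:
        clique = list(rng.choice(np.array(de_pool), size=clique_size, replace=False))
        for a_i in range(len(clique)):
            for b_i in range(a_i + 1, len(clique)):
                edge_rows.append((clique[a_i], clique[b_i], clique_score))
    lo, hi = background_score_range
    for _ in range(n_background_edges):
        a, b = rng.choice(len(targets), size=2, replace=False)
        edge_rows.append((targets[a], targets[b], float(np.round(rng.uniform(lo, hi), 3))))
    edges = pd.DataFrame(edge_rows, columns=["geneA", "geneB", "score"])

    drug_rows = [(g, planted_drug, True) for g in clique]
    for i in range(n_random_drug_rows):
        gene = targets[int(rng.integers(len(targets)))]
        drug_rows.append((gene, f"CPD{i:04d}", bool(rng.random() < 0.5)))
    drugs = pd.DataFrame(drug_rows, columns=["gene", "drug", "approved"])
    return edges, drugs
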