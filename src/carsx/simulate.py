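"""Synthetic responder/nonresponder cohorts with planted ground truth.

Two generators back the test bench for the whole pipeline:

``simulate_cross_species_cohort``
    Paired "human-like" and "mouse-like" bulk cohorts on the log2CPM scale.
    A set of signature genes is shifted between responders and nonresponders
    in *both* species (shared biology); one designated driver gene carries the
    largest shift so that a unique top-ranked gene exists, and the mouse-like
    matrix carries a global species batch offset. Gene symbols are uppercase
    on the human side and capitalized on the mouse side to exercise the
    case-insensitive ortholog-matching path.

``simulate_regulon_population``
    A single-population (single-cell-like) matrix in which each planted driver
    has a latent per-sample activity; positive targets follow the activity,
    negative targets oppose it, and the planted driver's activity differs
    between two sample groups. The driver's own mRNA either tracks its
    activity (default; the regulon is then learnable from expression) or is
    decoupled from it, which phenocopies a "hidden" driver whose activity
    changes without an expression change.

Expression is simulated directly on the log2 scale (normal noise around
per-gene baselines) because every downstream stage consumes log2CPM; an
optional Poisson-thinning export produces integer counts for testing the
count-normalization path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, Regulon

# Fixed substream offsets: each artifact gets its own child generator so that
# e.g. the truth layout is identical whether or not counts are exported.
_STREAM_TRUTH = 0
_STREAM_HUMAN = 1
_STREAM_MOUSE = 2
_STREAM_POPULATION = 3
_STREAM_COUNTS = 4
_STREAM_POPULATION_DATA = 5


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic cohorts.

    All expression-scale parameters are in log2 units.

    Attributes
    ----------
    n_genes : int
        Total genes per matrix.
    n_signature : int
        Number of true shared response genes (cross-species cohort).
    n_samples_per_group_per_species : int
        Responders and nonresponders per species (or per group for the
        single-population generator).
    effect_size : float
        log2 shift of the designated driver gene in responders; other
        signature genes receive magnitudes in Uniform(0.25, 0.35) x
        effect_size with random sign, so effect sizes are heterogeneous and
        the driver is the strongest shared signal.
    batch_shift : float
        Global log2 offset added to the mouse-like matrix (species batch).
    noise_sd : float
        Per-gene log2-scale residual standard deviation.
    n_drivers, targets_per_driver, frac_negative_targets : regulon geometry.
    driver_effect : float
        Latent-activity shift of the *first* planted driver between the two
        groups of the regulon population.
    driver_mrna_coupled : bool
        If True the driver's own mRNA equals its activity plus noise; if
        False it is independent noise (hidden-driver phenocopy).
    driver_mrna_shift : float
        Group shift applied to the planted driver's mRNA when decoupled
        (e.g. slightly negative for an activity-up / expression-down driver).
    seed : int
        Root seed; per-matrix substreams are derived by fixed offsets.
    structure_seed : int or None
        When set, the regulon *layout* (which genes are drivers/targets,
        baselines, target signs) is drawn from this seed while noise and
        latent activity follow ``seed`` — so a reference population and a
        comparison cohort can share planted regulons with independent data.
    """

    n_genes: int = 1000
    n_signature: int = 20
    n_samples_per_group_per_species: int = 20
    effect_size: float = 3.0
    batch_shift: float = 1.0
    noise_sd: float = 0.5
    n_drivers: int = 2
    targets_per_driver: int = 20
    frac_negative_targets: float = 0.4
    driver_effect: float = 2.0
    driver_mrna_coupled: bool = True
    driver_mrna_shift: float = 0.0
    seed: int = 0
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        for fname in ("n_genes", "n_signature", "n_samples_per_group_per_species",
                      "n_drivers", "targets_per_driver"):
            v = getattr(self, fname)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{fname} must be an integer >= 1, got {v!r}")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature must not exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd!r}")
        if not 0.0 <= self.frac_negative_targets <= 1.0:
            raise ValueError(
                f"frac_negative_targets must be in [0, 1], got {self.frac_negative_targets!r}")

    @classmethod
    def cross_species_defaults(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Default paired bulk-cohort conditions (20+20 samples/species)."""
        params = dict(n_genes=1000, n_signature=20,
                      n_samples_per_group_per_species=20, effect_size=3.0,
                      batch_shift=1.0, noise_sd=0.5, seed=seed)
        params.update(overrides)
        return cls(**params)

    @classmethod
    def regulon_defaults(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Default regulon-population conditions (2 drivers x 20 targets, 500 cells)."""
        params = dict(n_genes=200, n_signature=1,
                      n_samples_per_group_per_species=250, effect_size=0.0,
                      batch_shift=0.0, noise_sd=0.3, n_drivers=2,
                      targets_per_driver=20, frac_negative_targets=0.4,
                      driver_effect=2.0, seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class SimTruth:
    """Planted ground truth for a simulated cohort."""

    signature_genes: dict[str, int] = field(default_factory=dict)  # gene -> +/-1
    signature_effects: dict[str, float] = field(default_factory=dict)  # signed log2 shift
    driver_gene: str | None = None
    driver_regulons: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    group_labels: dict[str, str] = field(default_factory=dict)
    species_labels: dict[str, str] = field(default_factory=dict)
    latent_activity: pd.DataFrame | None = None  # drivers x samples

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_genes": self.signature_genes,
            "signature_effects": self.signature_effects,
            "driver_gene": self.driver_gene,
            "driver_regulons": {d: [[t, int(s)] for t, s in targets]
                                for d, targets in self.driver_regulons.items()},
            "group_labels": self.group_labels,
            "species_labels": self.species_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            signature_genes={k: int(v) for k, v in d["signature_genes"].items()},
            signature_effects={k: float(v) for k, v in d["signature_effects"].items()},
            driver_gene=d.get("driver_gene"),
            driver_regulons={k: [(t, int(s)) for t, s in v]
                             for k, v in d.get("driver_regulons", {}).items()},
            group_labels=d.get("group_labels", {}),
            species_labels=d.get("species_labels", {}),
        )


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def _mouse_case(symbol: str) -> str:
    return symbol.capitalize()


def simulate_cross_species_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Generate paired human-like / mouse-like responder vs nonresponder cohorts.

    Returns the two log2CPM-scale matrices and the planted truth. Deterministic
    given ``config`` (including ``seed``).
    """
    cfg = config
    n_g = cfg.n_genes
    n_per = cfg.n_samples_per_group_per_species

    rng_truth = np.random.default_rng([cfg.seed, _STREAM_TRUTH])
    genes_h = _gene_symbols(n_g)

    mu = rng_truth.normal(7.0, 2.0, size=n_g)  # typical log2CPM baselines

    sig_idx = np.sort(rng_truth.choice(n_g, size=cfg.n_signature, replace=False))
    directions = rng_truth.choice([-1, 1], size=cfg.n_signature)
    magnitudes = rng_truth.uniform(0.25, 0.35, size=cfg.n_signature) * cfg.effect_size
    # one randomly placed signature gene is the designated driver: full
    # effect, upregulated in responders; the rest carry smaller shifts so a
    # unique strongest shared signal exists
    driver_pos = int(rng_truth.integers(cfg.n_signature))
    directions[driver_pos] = 1
    magnitudes[driver_pos] = cfg.effect_size
    effects = np.zeros(n_g)
    effects[sig_idx] = directions * magnitudes

    truth = SimTruth(
        signature_genes={genes_h[i]: int(d) for i, d in zip(sig_idx, directions)},
        signature_effects={genes_h[i]: float(e)
                           for i, e in zip(sig_idx, effects[sig_idx])},
        driver_gene=genes_h[sig_idx[driver_pos]],
    )

    matrices = {}
    for species, stream, case_fn, prefix, batch in (
        ("human", _STREAM_HUMAN, str, "h", 0.0),
        ("mouse", _STREAM_MOUSE, _mouse_case, "m", cfg.batch_shift),
    ):
        rng = np.random.default_rng([cfg.seed, stream])
        samples = ([f"{prefix}.R{i + 1:02d}" for i in range(n_per)]
                   + [f"{prefix}.N{i + 1:02d}" for i in range(n_per)])
        responder = np.array([1] * n_per + [0] * n_per)
        x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_g, 2 * n_per))
        x += effects[:, None] * responder[None, :]
        x += batch
        values = pd.DataFrame(x, index=[case_fn(g) for g in genes_h], columns=samples)
        matrices[species] = ExpressionMatrix(values, "log2cpm", species)
        for s, r in zip(samples, responder):
            truth.group_labels[s] = "responder" if r else "nonresponder"
            truth.species_labels[s] = species

    return matrices["human"], matrices["mouse"], truth


def simulate_regulon_population(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a regulon-structured single-population expression matrix.

    Each driver has a standard-normal latent activity per sample; the first
    driver's activity is shifted by ``driver_effect`` in the responder group.
    Positive targets add the activity, negative targets subtract it, and
    off-regulon genes are independent noise.
    """
    cfg = config
    n_g = cfg.n_genes
    n_per = cfg.n_samples_per_group_per_species
    n_samples = 2 * n_per

    needed = cfg.n_drivers * (cfg.targets_per_driver + 1)
    if needed > n_g:
        raise ValueError(
            f"n_drivers * (targets_per_driver + 1) = {needed} exceeds n_genes = {n_g}")

    struct_rng = np.random.default_rng(
        [cfg.structure_seed if cfg.structure_seed is not None else cfg.seed,
         _STREAM_POPULATION])
    rng = np.random.default_rng([cfg.seed, _STREAM_POPULATION_DATA])
    genes = [_mouse_case(g) for g in _gene_symbols(n_g)]
    samples = ([f"c.R{i + 1:03d}" for i in range(n_per)]
               + [f"c.N{i + 1:03d}" for i in range(n_per)])
    responder = np.array([1] * n_per + [0] * n_per)

    perm = struct_rng.permutation(n_g)
    driver_idx = perm[:cfg.n_drivers]
    target_idx = perm[cfg.n_drivers:needed].reshape(cfg.n_drivers,
                                                    cfg.targets_per_driver)

    mu = struct_rng.normal(7.0, 2.0, size=n_g)
    n_neg = int(round(cfg.frac_negative_targets * cfg.targets_per_driver))
    sign_sets = [struct_rng.permutation(
        np.array([1] * (cfg.targets_per_driver - n_neg) + [-1] * n_neg))
        for _ in range(cfg.n_drivers)]

    x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_g, n_samples))
    activity = rng.normal(0.0, 1.0, size=(cfg.n_drivers, n_samples))
    activity[0] += cfg.driver_effect * responder

    truth = SimTruth()
    for d in range(cfg.n_drivers):
        gi = driver_idx[d]
        signs = sign_sets[d]
        for t, s in zip(target_idx[d], signs):
            x[t] += s * activity[d]
        if cfg.driver_mrna_coupled:
            x[gi] += activity[d]
        else:
            x[gi] += cfg.driver_mrna_shift * responder
        truth.driver_regulons[genes[gi]] = [
            (genes[t], int(s)) for t, s in zip(target_idx[d], signs)]
    truth.driver_gene = genes[driver_idx[0]]
    truth.latent_activity = pd.DataFrame(
        activity, index=[genes[i] for i in driver_idx], columns=samples)
    for s, r in zip(samples, responder):
        truth.group_labels[s] = "responder" if r else "nonresponder"
        truth.species_labels[s] = "mouse"

    values = pd.DataFrame(x, index=genes, columns=samples)
    return ExpressionMatrix(values, "log2cpm", "mouse"), truth


def true_regulons(truth: SimTruth, expr: ExpressionMatrix | None = None) -> dict[str, Regulon]:
    """Planted regulons as :class:`Regulon` objects with unit MI weights."""
    out = {}
    for driver, targets in truth.driver_regulons.items():
        t = pd.DataFrame({"target": [g for g, _ in targets],
                          "mi": 1.0,
                          "sign": [s for _, s in targets]})
        if expr is not None:
            t = t[t["target"].isin(expr.genes)]
        out[driver] = Regulon(driver, t)
    return out


def export_counts(expr: ExpressionMatrix, depth: float = 1e6,
                  seed: int = 0) -> ExpressionMatrix:
    """Poisson-thin a log2-scale matrix into an integer count matrix.

    Each sample's library composition is proportional to ``2**x`` and the
    expected library size is ``depth``. Used to exercise the
    count-normalization path; thinning adds sampling noise and the CPM
    composition constant, so the round-trip through ``log2cpm`` recovers the
    input up to a per-sample offset.
    """
    rng = np.random.default_rng([seed, _STREAM_COUNTS])
    linear = np.power(2.0, expr.values.to_numpy(dtype=float))
    comp = linear / linear.sum(axis=0, keepdims=True)
    counts = rng.poisson(depth * comp)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=expr.genes, columns=expr.samples),
        "raw_counts", expr.species)


def group_series(truth: SimTruth, samples) -> pd.Series:
    """Group labels for ``samples`` as a pandas Series."""
    return pd.Series({s: truth.group_labels[s] for s in samples}, name="group")


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
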