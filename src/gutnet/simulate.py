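"""Synthetic cohort generator with planted network ground truth.

Emulates a longitudinal three-arm study design (enteral nutrition vs.
parenteral nutrition with/without levofloxacin prophylaxis, sampled at three
timepoints) at the species relative-abundance level, so that every downstream
stage — filtering, signed Spearman networks, spin-glass modules, cohesion and
the leave-one-out keystone scan — can be exercised against a known truth.

The generative model is a Gaussian copula: a latent multivariate normal with
block-structured correlation (co-occurring species blocks, optionally
antagonistic block pairs with negative cross-correlation) is pushed through
log-normal marginals, scaled by group x timepoint fold changes, zero-inflated,
and closed to 100% per sample.  Because ranks are preserved by the monotone
marginal transform, the latent correlation targets translate directly into
Spearman structure downstream.

A planted *keystone* species carries the block's latent factor itself (the
other members load on it at sqrt(rho)) and receives a dominance weight that
makes it the dominant member of the community — emulating the ecological
situation where most of the community's cohesion runs through one taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GROUPS, TIMEPOINTS

__all__ = [
    "BlockSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "generate_pathway_table",
    "ground_truth_frame",
]


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-occurrence block: ``size`` species with pairwise latent
    correlation ``rho`` (in (0, 1])."""

    block_id: int
    size: int
    rho: float

    def __post_init__(self):
        if self.size < 2:
            raise ValueError(f"block {self.block_id}: need >= 2 members")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"block {self.block_id}: rho must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort.

    Blocks occupy the first ``sum(size)`` species indices in order; remaining
    species are independent fillers.  ``antagonist_pairs`` entries are
    ``(block_a, block_b, rho_neg)`` with ``rho_neg`` in [-1, 0): the target
    latent correlation between members of the two blocks.
    ``group_effects`` maps ``(group, timepoint)`` to ``{block_id: log2 fold
    change}`` multipliers applied to that block's abundances in that design
    cell.  ``keystone_spec`` entries are ``(species_index, dominance)`` with
    dominance > 1 scaling the keystone's abundance.
    """

    n_subjects_per_group: int = 10
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_species: int = 60
    blocks: tuple[BlockSpec, ...] = ()
    antagonist_pairs: tuple[tuple[int, int, float], ...] = ()
    group_effects: dict[tuple[str, str], dict[int, float]] = field(
        default_factory=dict)
    keystone_spec: tuple[tuple[int, float], ...] = ()
    zero_inflation_prob: float = 0.0
    dispersion: float = 1.0
    base_scale_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group < 1 or self.n_species < 1:
            raise ValueError("n_subjects_per_group and n_species must be positive")
        if sum(b.size for b in self.blocks) > self.n_species:
            raise ValueError("block member counts exceed n_species")
        if not 0.0 <= self.zero_inflation_prob < 1.0:
            raise ValueError("zero_inflation_prob must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate block ids")
        for a, b, r in self.antagonist_pairs:
            if a not in ids or b not in ids:
                raise ValueError(f"antagonist pair ({a}, {b}) names unknown blocks")
            if not -1.0 <= r < 0.0:
                raise ValueError(f"antagonist rho for ({a}, {b}) must be in [-1, 0)")
        membership = self.block_membership()
        for idx, w in self.keystone_spec:
            if membership.get(idx) is None:
                raise ValueError(f"keystone index {idx} is not in any block")
            if w <= 1:
                raise ValueError(f"keystone dominance must be > 1 (got {w})")

    def block_membership(self) -> dict[int, int]:
        """Species index -> block id for block members (fillers absent)."""
        out: dict[int, int] = {}
        pos = 0
        for b in self.blocks:
            for i in range(pos, pos + b.size):
                out[i] = b.block_id
            pos += b.size
        return out

    @property
    def n_samples(self) -> int:
        return len(self.groups) * len(self.timepoints) * self.n_subjects_per_group

    def species_names(self) -> list[str]:
        return [f"species_{i:03d}" for i in range(self.n_species)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated cohort."""

    block_labels: dict[str, int]          # species -> block id (members only)
    keystones: frozenset[str]
    expected_fold_changes: dict[tuple[str, str], dict[int, float]]


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-design defaults: 10 subjects per arm, 3 arms, 3 timepoints,
    60 species with two commensal blocks, one antagonistic pathobiont block
    that blooms under parenteral nutrition (strongest with prophylaxis), and
    one dominant planted keystone in the larger commensal block."""
    blocks = (
        BlockSpec(0, 10, 0.80),   # commensal block A (holds the keystone)
        BlockSpec(1, 8, 0.80),    # commensal block B
        BlockSpec(2, 8, 0.85),    # pathobiont block
    )
    effects: dict[tuple[str, str], dict[int, float]] = {
        ("PN_LVX_MINUS", "T1"): {0: -1.0, 1: -1.0, 2: 1.0},
        ("PN_LVX_MINUS", "T2"): {0: -1.0, 1: -1.0, 2: 1.0},
        ("PN_LVX_PLUS", "T1"): {0: -2.0, 1: -2.0, 2: 2.0},
        ("PN_LVX_PLUS", "T2"): {0: -2.0, 1: -2.0, 2: 2.0},
    }
    return SyntheticConfig(
        blocks=blocks,
        antagonist_pairs=((2, 0, -0.5),),
        group_effects=effects,
        keystone_spec=((0, 20.0),),
        zero_inflation_prob=0.05,
        dispersion=1.0,
        seed=seed,
    )


def _factor_correlation(config: SyntheticConfig) -> np.ndarray:
    """Correlation matrix of the latent block factors implied by the
    antagonist targets; rejects non-positive-definite constructions."""
    blocks = {b.block_id: b for b in config.blocks}
    order = [b.block_id for b in config.blocks]
    k = len(order)
    phi = np.eye(k)
    for a, b, r in config.antagonist_pairs:
        ia, ib = order.index(a), order.index(b)
        # member-level cross correlation r = sqrt(rho_a * rho_b) * phi_ab
        phi_ab = r / np.sqrt(blocks[a].rho * blocks[b].rho)
        if abs(phi_ab) > 1.0:
            raise ValueError(
                f"antagonist target {r} between blocks {a} and {b} is "
                f"unreachable given within-block rho "
                f"({blocks[a].rho}, {blocks[b].rho})")
        phi[ia, ib] = phi[ib, ia] = phi_ab
    try:
        np.linalg.cholesky(phi)
    except np.linalg.LinAlgError:
        offenders = [(a, b) for a, b, _ in config.antagonist_pairs]
        raise ValueError(
            "implied latent block-factor correlation matrix is not positive "
            f"definite; check antagonist pairs {offenders}") from None
    return phi


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Sample a full cohort.

    Returns ``(abundance, metadata, truth)`` where ``abundance`` is a
    samples x species percent table (each row sums to 100), ``metadata``
    has patient / group / timepoint per sample, and ``truth`` records the
    planted blocks, keystones and expected fold changes.  Identical config
    (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_sp, n_samples = config.n_species, config.n_samples
    names = config.species_names()
    membership = config.block_membership()
    keystone_idx = {i: w for i, w in config.keystone_spec}

    # per-species log abundance scale; a keystone's scale is pinned to
    # dominance x the expected species scale (exp(sd^2/2) for the log-normal
    # base), so its community share is set by the dominance weight alone
    base = rng.normal(0.0, config.base_scale_sd, n_sp)
    for i, w in keystone_idx.items():
        base[i] = np.log(w) + 0.5 * config.base_scale_sd ** 2

    # latent block factors (possibly cross-correlated), one draw per sample
    phi = _factor_correlation(config)
    order = [b.block_id for b in config.blocks]
    rho_of = {b.block_id: b.rho for b in config.blocks}
    chol = np.linalg.cholesky(phi) if order else np.zeros((0, 0))
    factors = rng.standard_normal((n_samples, len(order))) @ chol.T
    eps = rng.standard_normal((n_samples, n_sp))

    z = np.empty((n_samples, n_sp))
    for i in range(n_sp):
        b = membership.get(i)
        if b is None:
            z[:, i] = eps[:, i]
        elif i in keystone_idx:
            z[:, i] = factors[:, order.index(b)]
        else:
            rho = rho_of[b]
            z[:, i] = (np.sqrt(rho) * factors[:, order.index(b)]
                       + np.sqrt(1.0 - rho) * eps[:, i])

    raw = np.exp(base[None, :] + config.dispersion * z)

    # sample bookkeeping and group x timepoint fold changes
    sample_ids, patients, groups_col, tps_col = [], [], [], []
    row = 0
    for g in config.groups:
        for s in range(config.n_subjects_per_group):
            patient = f"{g}_P{s:02d}"
            for t in config.timepoints:
                sample_ids.append(f"{patient}_{t}")
                patients.append(patient)
                groups_col.append(g)
                tps_col.append(t)
                mult = config.group_effects.get((g, t), {})
                for block_id, lfc in mult.items():
                    cols = [i for i, bb in membership.items() if bb == block_id]
                    raw[row, cols] *= 2.0 ** lfc
                row += 1

    # zero inflation, then closure to percent scale
    if config.zero_inflation_prob > 0:
        mask = rng.random((n_samples, n_sp)) < config.zero_inflation_prob
        # never zero out an entire sample: keep each row's largest value
        keep = raw.argmax(axis=1)
        mask[np.arange(n_samples), keep] = False
        raw = np.where(mask, 0.0, raw)
    abundance = 100.0 * raw / raw.sum(axis=1, keepdims=True)

    table = pd.DataFrame(abundance, index=sample_ids, columns=names)
    table.index.name = "sample"
    metadata = pd.DataFrame(
        {"patient": patients, "group": groups_col, "timepoint": tps_col},
        index=pd.Index(sample_ids, name="sample"))

    truth = GroundTruth(
        block_labels={names[i]: b for i, b in membership.items()},
        keystones=frozenset(names[i] for i in keystone_idx),
        expected_fold_changes=dict(config.group_effects),
    )
    return table, metadata, truth


def generate_pathway_table(abundance: pd.DataFrame,
                           loadings: pd.DataFrame,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Couple a pathway table to species abundances.

    Each pathway column is ``abundance @ loadings`` (nonnegative weights per
    species) plus additive log-normal noise with log-sd ``noise_sd``
    (``noise_sd = 0`` means exactly no noise, so identity loadings reproduce
    the species column).  The result is renormalisable to CPM with
    :func:`gutnet.io.cpm_normalize`.
    """
    if not loadings.index.equals(pd.Index(abundance.columns)):
        if set(loadings.index) != set(abundance.columns):
            raise ValueError("loadings rows must match abundance species")
        loadings = loadings.loc[abundance.columns]
    if (loadings.to_numpy() < 0).any():
        raise ValueError("negative loadings are not allowed")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    values = abundance.to_numpy() @ loadings.to_numpy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.lognormal(0.0, noise_sd, values.shape)
    out = pd.DataFrame(values, index=abundance.index, columns=loadings.columns)
    out.index.name = "sample"
    return out


def ground_truth_frame(truth: GroundTruth, species: list[str]) -> pd.DataFrame:
    """Tabulate ground truth as (species, block, is_keystone) for export."""
    return pd.DataFrame({
        "species": species,
        "block": [truth.block_labels.get(sp, -1) for sp in species],
        "is_keystone": [sp in truth.keystones for sp in species],
    }).set_index("species")
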