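"""Seeded synthetic cohorts with planted enterotype, block, and group structure.

The generative model is a latent-factor log-normal composition sampled to
counts with a multinomial: per sample, each genus's log abundance is

    base log-mean (enterotype profile)
    + loading * block_factor          (one shared N(0,1) factor per block)
    + tracker_loading * anchor_factor (optional group-conditional trackers)
    + ln(2) * log2 group/stage effect
    + Normal(0, noise_sd)

after which the vector is exponentiated, normalized, and counts are drawn
as multinomial(depth, composition).  Blocks survive closure to relative
abundance in rank correlation, which is what the CAG stage needs.

Variance convention: the block factor contributes to a member genus's
*total* log-scale variance, i.e. the residual sd of a block member is
sqrt(noise_sd^2 - loading^2) (clamped at 0), so block and free genera have
the same total variance and planted effects the same signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance_io import (
    GROUP3_LEVELS,
    STAGE6_TO_GROUP3,
    CohortMetadata,
    GenusAbundanceTable,
    ValidationError,
)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "default_config",
    "generate_cohort",
    "ENTEROTYPES",
]

ENTEROTYPES = ("I", "II", "III")

_LN2 = float(np.log(2.0))

# default 60-genus panel ---------------------------------------------------

_DOMINANTS = ("Bacteroides", "Prevotella", "Escherichia")

_ANCHOR_BLOCK = (
    "Brenneria", "Cronobacter", "Erwinia", "Nitrobacter", "Paracoccus",
    "Pectobacterium", "Photorhabdus", "Shigella", "Sporosarcina", "Xenorhabdus",
)
_PATHOGEN_BLOCK = (
    "Fusobacterium", "Enterococcus", "Aeromonas", "Porphyromonas", "Morganella",
)
_BUTYRATE_BLOCK = (
    "Eubacterium", "Roseburia", "Faecalibacterium", "Oscillospira",
    "Coprococcus", "Butyrivibrio",
)
_BLOCK4 = (
    "Blautia", "Clostridium", "Klebsiella", "Veillonella",
    "Lactobacillus", "Leclercia", "Peptostreptococcus", "Synergistes",
)
_BLOCK5 = (
    "Desulfovibrio", "Enterobacter", "Proteus", "Serratia",
    "Providencia", "Hafnia", "Edwardsiella",
)
_BLOCK6 = ("Anaerostipes", "Collinsella", "Eggerthella", "Holdemania", "Megamonas")
_BLOCK7 = ("Mitsuokella", "Odoribacter", "Phascolarctobacterium", "Rothia")

_FREE = (
    "Haemophilus", "Citrobacter", "Ruminococcus", "Bilophila", "Pseudomonas",
    "Akkermansia", "Bifidobacterium", "Streptococcus", "Dorea",
    "Parabacteroides", "Alistipes", "Sutterella",
)

_DEFAULT_PANEL = (
    _DOMINANTS
    + _ANCHOR_BLOCK + _PATHOGEN_BLOCK + _BUTYRATE_BLOCK
    + _BLOCK4 + _BLOCK5 + _BLOCK6 + _BLOCK7
    + _FREE
)

_DEFAULT_BLOCKS = {
    "anchor": _ANCHOR_BLOCK,
    "pathogen": _PATHOGEN_BLOCK,
    "butyrate": _BUTYRATE_BLOCK,
    "block4": _BLOCK4,
    "block5": _BLOCK5,
    "block6": _BLOCK6,
    "block7": _BLOCK7,
}

# dominant-genus log-means: chosen so that with noise_sd=1.0 the intended
# enterotype label survives the threshold rule in >= 95% of samples
_DEFAULT_PROFILES = {
    "I": {"Bacteroides": 6.2},
    "II": {"Prevotella": 5.8},
    "III": {"Escherichia": 3.5},
}

_DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    **{g: {"cancer": 1.5} for g in _PATHOGEN_BLOCK},
    **{g: {"cancer": -1.5} for g in _BUTYRATE_BLOCK},
}

# stage-specific depletions driving the adenoma -> stage0 -> early transitions
_DEFAULT_STAGE_EFFECTS: dict[str, dict[str, float]] = {
    "Oscillospira": {"crc_stage0": -2.0, "crc_early": -2.0, "crc_late": -2.0},
    "Haemophilus": {"crc_early": -2.0, "crc_late": -2.0},
}

_ADENOMA_STAGES = ("small_adenoma", "advanced_adenoma")
_CANCER_STAGES = ("crc_stage0", "crc_early", "crc_late")


@dataclass
class SyntheticCohortConfig:
    """Full generative specification for one synthetic cohort.

    ``blocks`` maps block name -> member genera (pairwise disjoint);
    ``block_loadings`` gives each block's factor loading in [0, 1].
    ``group_effects`` / ``stage_effects`` map genus -> group3/stage6 ->
    log2 fold shift.  ``anchor_trackers`` maps genus -> group3 -> loading
    on the *anchor* block's factor, for planting correlation-switching
    genera.  ``genus_noise_sd`` overrides the residual sd per genus.
    """

    n_per_cell: int = 10
    genus_panel: tuple[str, ...] = _DEFAULT_PANEL
    enterotype_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PROFILES.items()}
    )
    blocks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_BLOCKS.items()}
    )
    block_loadings: dict[str, float] = field(
        default_factory=lambda: {k: 0.8 for k in _DEFAULT_BLOCKS}
    )
    # optional per-group3 loading overrides (block -> group3 -> loading),
    # for planting correlation structure expressed only in some groups
    block_group_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e in _DEFAULT_GROUP_EFFECTS.items()}
    )
    stage_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e in _DEFAULT_STAGE_EFFECTS.items()}
    )
    anchor_trackers: dict[str, dict[str, float]] = field(default_factory=dict)
    genus_noise_sd: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    depth: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        panel = list(self.genus_panel)
        if len(set(panel)) != len(panel):
            raise ValidationError("genus_panel contains duplicates")
        if self.n_per_cell < 1:
            raise ValidationError("n_per_cell must be >= 1")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        seen: set[str] = set()
        for name, members in self.blocks.items():
            members = tuple(members)
            unknown = set(members) - set(panel)
            if unknown:
                raise ValidationError(f"block {name!r} has non-panel genera {sorted(unknown)}")
            if seen & set(members):
                raise ValidationError(f"block {name!r} overlaps another block")
            seen |= set(members)
            lam = self.block_loadings.get(name, 0.0)
            if not 0.0 <= lam <= 1.0:
                raise ValidationError(f"block loading for {name!r} must be in [0, 1]")
        for name, per_group in self.block_group_loadings.items():
            if name not in self.blocks:
                raise ValidationError(f"block_group_loadings references unknown block {name!r}")
            for grp, lam in per_group.items():
                if grp not in GROUP3_LEVELS:
                    raise ValidationError(f"unknown group {grp!r} in block_group_loadings")
                if not 0.0 <= lam <= 1.0:
                    raise ValidationError(f"loading override for {name!r}/{grp!r} not in [0, 1]")
        for et in self.enterotype_profiles:
            if et not in ENTEROTYPES:
                raise ValidationError(f"unknown enterotype {et!r} in profiles")
        for mapping, levels, what in (
            (self.group_effects, set(GROUP3_LEVELS), "group_effects"),
            (self.stage_effects, set(STAGE6_TO_GROUP3), "stage_effects"),
        ):
            for genus, effects in mapping.items():
                if genus not in panel:
                    raise ValidationError(f"{what} references non-panel genus {genus!r}")
                bad = set(effects) - levels
                if bad:
                    raise ValidationError(f"{what}[{genus!r}] has unknown levels {sorted(bad)}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated cohort: what was planted where."""

    enterotype: dict  # sample_id -> intended enterotype
    group3: dict  # sample_id -> group
    stage6: dict  # sample_id -> stage
    blocks: dict  # block name -> member genera
    effect_sign: dict  # genus -> group3 -> +1 / -1

    def to_json_dict(self) -> dict:
        return {
            "enterotype": self.enterotype,
            "group3": self.group3,
            "stage6": self.stage6,
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "effect_sign": self.effect_sign,
        }


def default_config() -> SyntheticCohortConfig:
    """The documented default configuration (deterministic)."""
    return SyntheticCohortConfig()


def _stage_for(group: str, index_in_cell: int) -> str:
    if group == "normal":
        return "normal"
    if group == "adenoma":
        return _ADENOMA_STAGES[index_in_cell % len(_ADENOMA_STAGES)]
    return _CANCER_STAGES[index_in_cell % len(_CANCER_STAGES)]


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> tuple[GenusAbundanceTable, CohortMetadata, SyntheticTruth]:
    """Generate one cohort: count table, metadata, and planted truth.

    Samples are laid out over the 3 group x 3 enterotype grid with
    ``n_per_cell`` samples per cell; identical (config, seed) pairs
    produce bit-identical output.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    panel = list(config.genus_panel)
    n_genera = len(panel)
    gidx = {g: i for i, g in enumerate(panel)}

    noise_sd = np.full(n_genera, float(config.noise_sd))
    for g, sd in config.genus_noise_sd.items():
        noise_sd[gidx[g]] = float(sd)
    # block members: factor variance counts toward total residual variance
    for name, members in config.blocks.items():
        lam = config.block_loadings.get(name, 0.0)
        for g in members:
            i = gidx[g]
            noise_sd[i] = float(np.sqrt(max(noise_sd[i] ** 2 - lam**2, 0.0)))

    base = {
        et: np.array(
            [config.enterotype_profiles.get(et, {}).get(g, 0.0) for g in panel]
        )
        for et in ENTEROTYPES
    }

    block_names = list(config.blocks)
    block_member_idx = {
        name: np.array([gidx[g] for g in config.blocks[name]], dtype=int)
        for name in block_names
    }

    # per-(group, stage) log2 effects folded into one vector per stage6 label
    def effect_vector(group: str, stage: str) -> np.ndarray:
        eff = np.zeros(n_genera)
        for g, per_group in config.group_effects.items():
            eff[gidx[g]] += per_group.get(group, 0.0)
        for g, per_stage in config.stage_effects.items():
            eff[gidx[g]] += per_stage.get(stage, 0.0)
        return eff * _LN2

    rows = []
    meta_rows = []
    truth_et: dict = {}
    truth_group: dict = {}
    truth_stage: dict = {}
    sample_counter = 0
    for group in GROUP3_LEVELS:
        for et in ENTEROTYPES:
            for i in range(config.n_per_cell):
                sample_counter += 1
                sid = f"S{sample_counter:04d}"
                stage = _stage_for(group, i)
                factors = rng.standard_normal(len(block_names))
                eps = rng.standard_normal(n_genera) * noise_sd
                log_ab = base[et] + effect_vector(group, stage) + eps
                for b, name in enumerate(block_names):
                    lam = config.block_group_loadings.get(name, {}).get(
                        group, config.block_loadings.get(name, 0.0)
                    )
                    log_ab[block_member_idx[name]] += lam * factors[b]
                if config.anchor_trackers and "anchor" in config.blocks:
                    anchor_f = factors[block_names.index("anchor")]
                    for g, per_group in config.anchor_trackers.items():
                        log_ab[gidx[g]] += per_group.get(group, 0.0) * anchor_f
                comp = np.exp(log_ab - log_ab.max())
                comp /= comp.sum()
                counts = rng.multinomial(config.depth, comp)
                rows.append(counts)
                meta_rows.append(
                    {"sample_id": sid, "stage6": stage, "gender": "M" if rng.random() < 0.5 else "F"}
                )
                truth_et[sid] = et
                truth_group[sid] = STAGE6_TO_GROUP3[stage]
                truth_stage[sid] = stage

    sample_ids = [m["sample_id"] for m in meta_rows]
    table = GenusAbundanceTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=panel), "counts"
    )
    meta = CohortMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id")
    )
    effect_sign = {
        g: {grp: (1 if v > 0 else -1) for grp, v in per_group.items() if v != 0}
        for g, per_group in config.group_effects.items()
    }
    truth = SyntheticTruth(
        enterotype=truth_et,
        group3=truth_group,
        stage6=truth_stage,
        blocks={k: tuple(v) for k, v in config.blocks.items()},
        effect_sign=effect_sign,
    )
    return table, meta, truth
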