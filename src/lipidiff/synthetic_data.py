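"""Synthetic lipidomics datasets with known ground truth.

Emulates the structure of a small skin-cancer lipidomics study: three
groups (cSCC and BCC tumors plus healthy skin) totalling 13 samples from
12 patients, 309 identified lipid ions of which 168 carry reliable A/B
identification grades, log-normal intensities, class-structured planted
group effects, sporadic missing values, and occasional "(rep)" duplicate
ions of the same base lipid.

Intensities follow a log-normal model: each lipid has a baseline log10
intensity drawn once, each sample adds the group's planted log2 effect
(converted to log10) and i.i.d. normal noise on the log10 scale. The
model is deliberately simple — positive, right-skewed intensities with
multiplicative noise — and makes truth labels exact, so recovery and
calibration of the differential pipeline can be tested without any
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_preprocess import IntensityTable, SampleMeta
from .nomenclature import classify_category, parse_lipid_name

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RecoveryReport",
    "default_paper_like_spec",
    "null_spec",
    "generate_dataset",
    "truth_recovery_report",
]

LOG10_2 = math.log10(2.0)

#: chains per lipid class, and whether the first chain is a sphingoid base
_CLASS_SHAPE = {
    "TG": (3, False),
    "DG": (2, False),
    "PC": (2, False),
    "PI": (2, False),
    "PS": (2, False),
    "Cer": (2, True),
    "CerG2": (2, True),
    "LPC": (1, False),
    "LPE": (1, False),
    "LPI": (1, False),
}

#: default class composition of the 168 reliably identified (A/B) lipids;
#: triglycerides dominate (65), with diglycerides, diacyl phospholipids,
#: lyso-phospholipids and (glycosyl)ceramides making up the rest.
DEFAULT_CLASS_MIX = {
    "TG": 65 / 168,
    "PC": 25 / 168,
    "DG": 20 / 168,
    "Cer": 12 / 168,
    "LPC": 12 / 168,
    "PI": 10 / 168,
    "PS": 8 / 168,
    "LPE": 6 / 168,
    "CerG2": 5 / 168,
    "LPI": 5 / 168,
}

#: planted log2 shifts relative to the reference (healthy) group:
#: diglycerides strongly down in both tumors, diacyl phospholipids up in
#: BCC, lyso-phospholipids up in cSCC; all other classes null.
DEFAULT_EFFECT_MAP = {
    ("DG", "cSCC"): -2.0,
    ("DG", "BCC"): -2.0,
    ("PC", "BCC"): 1.5,
    ("PI", "BCC"): 1.5,
    ("PS", "BCC"): 1.5,
    ("LPC", "cSCC"): 1.5,
    ("LPE", "cSCC"): 1.5,
    ("LPI", "cSCC"): 1.5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated study.

    ``effect_map`` keys are ``(class_code_or_category, group)`` pairs and
    values are log2 intensity shifts relative to ``reference_group``;
    class codes take precedence over category names when both match.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"cSCC": 4, "BCC": 6, "Healthy": 3}
    )
    reference_group: str = "Healthy"
    n_lipids_ab: int = 168
    n_lipids_cd: int = 141
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    effect_map: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP)
    )
    noise_sd: float = 0.1
    missing_rate: float = 0.02
    replicate_rate: float = 0.03
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        if any(n < 0 for n in (self.n_lipids_ab, self.n_lipids_cd)):
            raise ValueError("lipid counts must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.reference_group not in self.group_sizes:
            raise ValueError(
                f"reference group {self.reference_group!r} absent from group_sizes"
            )

    @property
    def n_lipids(self) -> int:
        return self.n_lipids_ab + self.n_lipids_cd

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def effect_for(self, class_code: str, group: str) -> float:
        """Planted log2 shift of a lipid class in a group (0 for reference)."""
        if group == self.reference_group:
            return 0.0
        if (class_code, group) in self.effect_map:
            return self.effect_map[(class_code, group)]
        category = classify_category(class_code).value
        return self.effect_map.get((category, group), 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Per-lipid planted log2 effects relative to the reference group."""

    effects: pd.DataFrame  # index: lipid name; columns: groups
    reference_group: str

    def log2_difference(self, group1: str, group2: str) -> pd.Series:
        """True log2 fold change of group1 over group2, per lipid."""
        return self.effects[group1] - self.effects[group2]

    def is_differential(self, group1: str, group2: str) -> pd.Series:
        return self.log2_difference(group1, group2) != 0.0


class RecoveryReport(NamedTuple):
    sensitivity: float  # NaN when no lipid is planted differential
    specificity: float  # NaN when every lipid is planted differential


def default_paper_like_spec(seed: int = 0) -> SyntheticSpec:
    """The default 13-sample, 309-lipid study emulation.

    Group sizes 4 (cSCC) / 6 (BCC) / 3 (Healthy); 168 grade-A/B lipids
    (65 of them triglycerides) plus 141 grade-C/D lipids; planted trends
    of ~-2 log2 for diglycerides in both tumors, +1.5 log2 for diacyl
    phospholipids in BCC and for lyso-phospholipids in cSCC.
    Triglycerides are deliberately left null in BCC.
    """
    return SyntheticSpec(seed=seed)


def null_spec(seed: int = 0) -> SyntheticSpec:
    """The default design with every planted effect removed (global null)."""
    return replace(default_paper_like_spec(seed=seed), effect_map={})


# -- name generation -------------------------------------------------------

_CARBONS = (14, 16, 18, 20, 22, 24)
_SPHINGOID_BASES = ((18, 1), (18, 2))


def _largest_remainder(proportions: dict[str, float], total: int) -> dict[str, int]:
    """Integer apportionment that always hits ``total`` exactly."""
    raw = {k: p * total for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    shortfall = total - sum(counts.values())
    by_frac = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in by_frac[:shortfall]:
        counts[k] += 1
    return counts


def _random_chain(rng: np.random.Generator, sphingoid: bool) -> str:
    if sphingoid:
        c, d = _SPHINGOID_BASES[rng.integers(len(_SPHINGOID_BASES))]
        return f"d{c}:{d}"
    c = int(rng.choice(_CARBONS))
    d = int(rng.integers(0, 5))
    suffix = "e" if rng.random() < 0.05 else ""
    return f"{c}:{d}{suffix}"


def _generate_names(rng: np.random.Generator, class_counts: dict[str, int],
                    taken: set[str]) -> list[str]:
    names: list[str] = []
    for class_code in sorted(class_counts):
        n_chains, sphingoid_first = _CLASS_SHAPE.get(class_code, (2, False))
        for _ in range(class_counts[class_code]):
            for _attempt in range(10_000):
                chains = [
                    _random_chain(rng, sphingoid_first and k == 0)
                    for k in range(n_chains)
                ]
                name = f"{class_code}({'/'.join(chains)})"
                if name not in taken:
                    break
            else:  # pragma: no cover - name space far exceeds defaults
                raise RuntimeError(f"cannot draw a fresh {class_code} name")
            taken.add(name)
            names.append(name)
    return names


def _inject_replicates(rng: np.random.Generator, names: list[str], rate: float) -> list[str]:
    """Turn ~rate of the rows into '(rep)' twins of same-class rows."""
    n_rep = int(round(rate * len(names)))
    if n_rep == 0:
        return names
    out = list(names)
    candidates = list(range(len(names)))
    rng.shuffle(candidates)
    used: set[int] = set()
    made = 0
    for idx in candidates:
        if made >= n_rep:
            break
        if idx in used:
            continue
        base_class = out[idx].split("(", 1)[0]
        partners = [
            j for j in range(len(out))
            if j != idx and j not in used
            and out[j].split("(", 1)[0] == base_class
            and not out[j].endswith("(rep)")
        ]
        if not partners:
            continue
        j = partners[int(rng.integers(len(partners)))]
        out[idx] = out[j] + "(rep)"
        used.update((idx, j))
        made += 1
    return out


# -- dataset generation ----------------------------------------------------


def _build_samples(spec: SyntheticSpec) -> list[SampleMeta]:
    samples: list[SampleMeta] = []
    patient = 0
    for group in spec.group_sizes:
        size = spec.group_sizes[group]
        for k in range(size):
            # the reference group's last sample shares its donor with the
            # previous one (e.g. 2 healthy patients contributing 3 samples)
            if group == spec.reference_group and k == size - 1 and size >= 2:
                pid = patient
            else:
                patient += 1
                pid = patient
            samples.append(SampleMeta(f"{group}_{k + 1}", group, f"P{pid:02d}"))
    return samples


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[IntensityTable, list[SampleMeta], GroundTruth]:
    """Draw one full synthetic study; deterministic given ``spec.seed``.

    Returns the intensity table (grades assigned so exactly
    ``spec.n_lipids_ab`` rows are A/B), the sample metadata, and the
    ground-truth planted effects. Missingness is re-drawn per row until
    every group keeps at least two observed values, so every lipid stays
    testable in every pairwise comparison.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _build_samples(spec)
    groups = [s.group for s in samples]

    taken: set[str] = set()
    names_ab = _generate_names(rng, _largest_remainder(spec.class_mix, spec.n_lipids_ab), taken)
    names_cd = _generate_names(rng, _largest_remainder(spec.class_mix, spec.n_lipids_cd), taken)
    names_ab = _inject_replicates(rng, names_ab, spec.replicate_rate)
    names_cd = _inject_replicates(rng, names_cd, spec.replicate_rate)

    grades = list(rng.choice(["A", "B"], size=len(names_ab))) + list(
        rng.choice(["C", "D"], size=len(names_cd))
    )
    names = names_ab + names_cd
    order = rng.permutation(len(names))
    names = [names[i] for i in order]
    grades = [grades[i] for i in order]

    # '(rep)' twins share the baseline and effects of their base lipid
    baselines: dict[str, float] = {}
    n, m = len(names), len(samples)
    log10 = np.empty((n, m))
    truth_rows = {}
    for i, name in enumerate(names):
        base = name[:-5] if name.endswith("(rep)") else name
        if base not in baselines:
            baselines[base] = spec.baseline_log_mean + spec.baseline_log_sd * rng.standard_normal()
        class_code = parse_lipid_name(name).class_code
        effects = {g: spec.effect_for(class_code, g) for g in spec.group_sizes}
        truth_rows[name] = effects
        shifts = np.array([effects[g] for g in groups]) * LOG10_2
        log10[i] = baselines[base] + shifts + spec.noise_sd * rng.standard_normal(m)

    intensities = 10.0 ** log10

    group_cols = {
        g: np.array([j for j, gg in enumerate(groups) if gg == g])
        for g in spec.group_sizes
    }
    mask = np.zeros((n, m), dtype=bool)
    if spec.missing_rate > 0:
        for i in range(n):
            for _attempt in range(1000):
                row = rng.random(m) < spec.missing_rate
                ok = all((~row[cols]).sum() >= 2 for cols in group_cols.values())
                if ok:
                    mask[i] = row
                    break
    intensities = intensities.copy()
    intensities[mask] = np.nan

    table = IntensityTable(
        lipids=names,
        grades=grades,
        intensities=intensities,
        missing_mask=mask,
        samples=samples,
    )
    truth = GroundTruth(
        effects=pd.DataFrame.from_dict(truth_rows, orient="index").loc[names],
        reference_group=spec.reference_group,
    )
    return table, samples, truth


# -- evaluation ------------------------------------------------------------


def truth_recovery_report(
    results_by_comparison: dict,
    truth: GroundTruth,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Sensitivity and specificity of volcano calls against planted truth.

    A planted lipid counts as recovered only when it is volcano-significant
    in the correct direction for its comparison; a null lipid counts as a
    false call when it is volcano-significant either way. ``alpha`` is
    informational here — calls are taken as made by the volcano classifier.
    Aggregated over all supplied comparisons.
    """
    tp = fn = tn = fp = 0
    for spec, results in results_by_comparison.items():
        diff = truth.log2_difference(spec.group1, spec.group2)
        for r in results:
            true_effect = diff.get(r.lipid, 0.0)
            if true_effect != 0.0:
                want = "up" if true_effect > 0 else "down"
                if r.call == want:
                    tp += 1
                else:
                    fn += 1
            else:
                if r.call == "not_significant":
                    tn += 1
                else:
                    fp += 1
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return RecoveryReport(sensitivity, specificity)
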