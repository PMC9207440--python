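"""Synthetic qPCR / measurement time-series generator with known ground truth.

The generator reproduces the design of a three-zeitgeber daily-rhythm study in
goldfish: three experimental groups (12L:12D with scheduled feeding at ZT 2,
12L:12D with random feeding, constant darkness with scheduled feeding at CT 2),
seven sampling times across a 24-h cycle (ZT/CT 3, 7, 11, 15, 19, 23 and 3 of
the next day, labelled "3b" and generated at t = 27 h), and 5-7 fish per group
and time.  Each gene follows a sinusoid ``M + A cos(pi/12 (t - acrophase_h))``
so that every downstream stage (2^-ddCt quantification, ANOVA/SNK, cosinor,
rhythm call) can be tested against known truth.

Two output kinds are supported: ``"ct"`` emits duplicate-well cycle-threshold
values for every target gene plus a stable reference gene (eef-1a1-like), so
the table must pass through :func:`rhythmq.quantify.compute_fold_change`;
``"measurement"`` emits the expression/measurement values directly (the plasma
glucose path).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DesignGrid",
    "GeneTruth",
    "QpcrNoiseModel",
    "ScenarioConfig",
    "generate_dataset",
    "generate_random_feeding_schedule",
    "glucose_scenario",
    "study_scenario",
    "true_expression",
]

OMEGA = np.pi / 12.0

DEFAULT_GROUPS = ("LD_scheduled", "LD_random", "DD_scheduled")
DEFAULT_TIMES_H = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0)
DEFAULT_TIME_LABELS = ("ZT3", "ZT7", "ZT11", "ZT15", "ZT19", "ZT23", "ZT3b")


@dataclass(frozen=True)
class DesignGrid:
    """Sampling design: groups x times x tissues with per-cell sample sizes.

    ``times_h`` are hours since lights-on (ZT) or subjective dawn (CT); the
    follow-up sample of the next morning is carried at 27 h, phase-equivalent
    to 3 h under the fixed 24-h period.  ``n_per_time`` is either one integer
    for every cell or a mapping ``(group, time_label) -> n`` (the study used
    5-7 fish per cell).
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    time_labels: tuple[str, ...] = DEFAULT_TIME_LABELS
    n_per_time: int | Mapping[tuple[str, str], int] = 7
    tissues: tuple[str, ...] = ("hypothalamus", "liver")
    light_regime: Mapping[str, str] = field(
        default_factory=lambda: {
            "LD_scheduled": "LD",
            "LD_random": "LD",
            "DD_scheduled": "DD",
        }
    )
    feeding_regime: Mapping[str, str] = field(
        default_factory=lambda: {
            "LD_scheduled": "scheduled",
            "LD_random": "random",
            "DD_scheduled": "scheduled",
        }
    )

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.time_labels):
            raise ValueError("times_h and time_labels must have equal length")
        if len(set(self.time_labels)) != len(self.time_labels):
            raise ValueError("time labels must be unique")
        t = np.asarray(self.times_h, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times_h must be strictly increasing")
        for g, lbl in self.iter_cells():
            n = self.n_at(g, lbl)
            if n < 2:
                raise ValueError(
                    f"n_per_time must be >= 2 (variance must be estimable); "
                    f"got {n} for cell ({g}, {lbl})"
                )

    def iter_cells(self):
        for g in self.groups:
            for lbl in self.time_labels:
                yield g, lbl

    def n_at(self, group: str, time_label: str) -> int:
        if isinstance(self.n_per_time, Mapping):
            return int(self.n_per_time[(group, time_label)])
        return int(self.n_per_time)

    def time_of(self, time_label: str) -> float:
        return float(self.times_h[self.time_labels.index(time_label)])


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth sinusoid of one gene: mean level M, amplitude A, peak time.

    The mean trajectory is ``M + A * cos(pi/12 * (t - acrophase_h))`` in
    expression fold units.  ``biological_noise_sd`` is the between-fish spread:
    on the log2 scale (default noise model) or in fold units (additive model).
    """

    gene: str
    mesor: float
    amplitude: float = 0.0
    acrophase_h: float = 0.0
    biological_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mesor <= 0:
            raise ValueError(f"gene {self.gene!r}: mesor must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"gene {self.gene!r}: amplitude must be >= 0")
        if not 0.0 <= self.acrophase_h < 24.0:
            raise ValueError(f"gene {self.gene!r}: acrophase_h must be in [0, 24)")
        if self.biological_noise_sd < 0:
            raise ValueError(f"gene {self.gene!r}: biological_noise_sd must be >= 0")

    @property
    def is_rhythmic(self) -> bool:
        return self.amplitude > 0.0


def true_expression(truth: GeneTruth, times_h) -> np.ndarray:
    """Noise-free mean trajectory of a gene at the given times."""
    t = np.asarray(times_h, dtype=float)
    return truth.mesor + truth.amplitude * np.cos(OMEGA * (t - truth.acrophase_h))


@dataclass(frozen=True)
class QpcrNoiseModel:
    """Cycle-threshold noise structure of the qPCR layer.

    ``ct_base_target`` is the target-gene Ct corresponding to expression
    fold 1 (Ct = ct_base_target - log2(expression), amplification efficiency
    fixed at 2).  The reference gene is time-invariant in expectation with
    between-fish sd ``ref_sd``; ``technical_sd`` is the duplicate-well spread.
    Ct draws are clamped to (0, 40] (the 40-cycle run limit).
    """

    ct_base_ref: float = 16.0
    ref_sd: float = 0.0
    ct_base_target: float = 24.0
    technical_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise sd values must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete generative scenario: design, per-tissue gene truths, noise, seed.

    ``genes`` maps a tissue (or a ``(tissue, group)`` pair, for scenarios where
    rhythmicity differs between groups — e.g. arrhythmic under constant
    darkness) to its list of :class:`GeneTruth`; a plain list applies to all
    tissues and groups.  ``noise_scale`` selects the biological noise model:
    ``"log2"`` (multiplicative, keeps expression positive; default) or
    ``"additive"`` (Gaussian in measurement units).
    """

    design: DesignGrid = field(default_factory=DesignGrid)
    genes: Sequence[GeneTruth] | Mapping = field(default_factory=list)
    noise: QpcrNoiseModel = field(default_factory=QpcrNoiseModel)
    seed: int = 0
    output_kind: str = "ct"
    noise_scale: str = "log2"
    reference_gene: str = "eef-1a1"

    def __post_init__(self) -> None:
        if self.output_kind not in ("ct", "measurement"):
            raise ValueError("output_kind must be 'ct' or 'measurement'")
        if self.noise_scale not in ("log2", "additive"):
            raise ValueError("noise_scale must be 'log2' or 'additive'")

    def __deepcopy__(self, memo):
        # immutable; pandas deep-copies DataFrame.attrs on nearly every
        # operation, which would otherwise recurse through every GeneTruth
        return self

    def truths_for(self, tissue: str, group: str) -> list[GeneTruth]:
        if isinstance(self.genes, Mapping):
            if (tissue, group) in self.genes:
                return list(self.genes[(tissue, group)])
            if tissue in self.genes:
                return list(self.genes[tissue])
            return []
        return list(self.genes)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = self.design
        genes: object
        if isinstance(self.genes, Mapping):
            genes = {
                (k if isinstance(k, str) else "|".join(k)): [
                    dataclasses.asdict(t) for t in v
                ]
                for k, v in self.genes.items()
            }
        else:
            genes = [dataclasses.asdict(t) for t in self.genes]
        return {
            "design": {
                "groups": list(d.groups),
                "times_h": [float(t) for t in d.times_h],
                "time_labels": list(d.time_labels),
                "n_per_time": (
                    {f"{g}|{lbl}": n for (g, lbl), n in d.n_per_time.items()}
                    if isinstance(d.n_per_time, Mapping)
                    else int(d.n_per_time)
                ),
                "tissues": list(d.tissues),
                "light_regime": dict(d.light_regime),
                "feeding_regime": dict(d.feeding_regime),
            },
            "genes": genes,
            "noise": dataclasses.asdict(self.noise),
            "seed": int(self.seed),
            "output_kind": self.output_kind,
            "noise_scale": self.noise_scale,
            "reference_gene": self.reference_gene,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        dd = d["design"]
        npt = dd.get("n_per_time", 7)
        if isinstance(npt, Mapping):
            npt = {tuple(k.split("|")): int(v) for k, v in npt.items()}
        design = DesignGrid(
            groups=tuple(dd["groups"]),
            times_h=tuple(float(t) for t in dd["times_h"]),
            time_labels=tuple(dd["time_labels"]),
            n_per_time=npt,
            tissues=tuple(dd.get("tissues", ("hypothalamus", "liver"))),
            light_regime=dict(dd.get("light_regime", {})),
            feeding_regime=dict(dd.get("feeding_regime", {})),
        )
        raw = d["genes"]
        genes: object
        if isinstance(raw, Mapping):
            genes = {
                (tuple(k.split("|")) if "|" in k else k): [GeneTruth(**t) for t in v]
                for k, v in raw.items()
            }
        else:
            genes = [GeneTruth(**t) for t in raw]
        return cls(
            design=design,
            genes=genes,
            noise=QpcrNoiseModel(**d.get("noise", {})),
            seed=int(d.get("seed", 0)),
            output_kind=d.get("output_kind", "ct"),
            noise_scale=d.get("noise_scale", "log2"),
            reference_gene=d.get("reference_gene", "eef-1a1"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _validate_truths(config: ScenarioConfig) -> None:
    needs_positive = config.output_kind == "ct" or config.noise_scale == "log2"
    for tissue in config.design.tissues:
        for group in config.design.groups:
            for truth in config.truths_for(tissue, group):
                trough = truth.mesor - truth.amplitude
                if trough < 0 or (needs_positive and trough <= 0):
                    raise ValueError(
                        f"gene {truth.gene!r} ({tissue}, {group}): mesor - amplitude "
                        f"= {trough:g} implies non-positive expected expression; "
                        "reduce the amplitude or raise the mesor"
                    )


def generate_dataset(config: ScenarioConfig) -> pd.DataFrame:
    """Generate a tidy long-format dataset for a scenario.

    Returns a DataFrame with columns ``sample_id, group, tissue, gene,
    time_label, time_h, replicate`` and ``ct`` (output_kind "ct": duplicate
    wells per fish x gene, plus the reference gene) or ``value`` (output_kind
    "measurement": one record per fish x gene).  The generating
    :class:`ScenarioConfig` is embedded as ``df.attrs["scenario"]`` so that
    parameter-recovery reports can compare estimates against truth.  The same
    config (seed included) always produces an identical table.
    """
    _validate_truths(config)
    rng = np.random.default_rng(config.seed)
    d = config.design
    noise = config.noise
    ct_mode = config.output_kind == "ct"
    rows: list[tuple] = []

    for group in d.groups:
        for lbl in d.time_labels:
            t = d.time_of(lbl)
            n = d.n_at(group, lbl)
            for i in range(n):
                sample_id = f"{group}-{lbl}-{i + 1:02d}"
                for tissue in d.tissues:
                    if ct_mode:
                        ref_level = noise.ct_base_ref + (
                            rng.normal(0.0, noise.ref_sd) if noise.ref_sd else 0.0
                        )
                        for rep in (1, 2):
                            ct = ref_level + (
                                rng.normal(0.0, noise.technical_sd)
                                if noise.technical_sd
                                else 0.0
                            )
                            rows.append(
                                (sample_id, group, tissue, config.reference_gene,
                                 lbl, t, rep, float(np.clip(ct, np.nextafter(0, 1), 40.0)))
                            )
                    for truth in config.truths_for(tissue, group):
                        mu = float(true_expression(truth, t))
                        sd = truth.biological_noise_sd
                        if sd == 0.0:
                            expr = mu
                        elif config.noise_scale == "log2":
                            expr = float(2.0 ** (np.log2(mu) + rng.normal(0.0, sd)))
                        else:
                            expr = float(mu + rng.normal(0.0, sd))
                        if ct_mode:
                            # floor keeps log2 defined; equivalent to the Ct <= 40 clamp
                            expr = max(expr, 2.0 ** (noise.ct_base_target - 40.0))
                            level = noise.ct_base_target - np.log2(expr)
                            for rep in (1, 2):
                                ct = level + (
                                    rng.normal(0.0, noise.technical_sd)
                                    if noise.technical_sd
                                    else 0.0
                                )
                                rows.append(
                                    (sample_id, group, tissue, truth.gene, lbl, t,
                                     rep, float(np.clip(ct, np.nextafter(0, 1), 40.0)))
                                )
                        else:
                            rows.append(
                                (sample_id, group, tissue, truth.gene, lbl, t, 1, expr)
                            )

    value_col = "ct" if ct_mode else "value"
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "tissue", "gene", "time_label", "time_h",
                 "replicate", value_col],
    )
    df.attrs["scenario"] = config
    return df


def generate_random_feeding_schedule(days: int, seed: int) -> np.ndarray:
    """Random feeding schedule: one feeding per day, uniform over the 24-h day.

    Models the random-feeding group: food arrives once in every 24-h day at a
    time drawn uniformly from [0, 24), so feeding never skips a day and the
    time of day carries no periodic information.  Returns absolute hours since
    the start of day 0 (``24*d + u_d``), reproducible under ``seed``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(0.0, 24.0, size=days)
    return 24.0 * np.arange(days) + offsets


# ---------------------------------------------------------------------------
# Ready-made scenarios


def _clock_truths(specs, amp_scale=1.0, noise_sd=0.18) -> list[GeneTruth]:
    out = []
    for gene, mesor, amp, acro in specs:
        a = amp * amp_scale
        out.append(
            GeneTruth(gene=gene, mesor=mesor, amplitude=a,
                      acrophase_h=acro, biological_noise_sd=noise_sd)
        )
    return out


def study_scenario(seed: int = 0, n_per_time: int = 7,
                   technical_sd: float = 0.12, ref_sd: float = 0.15) -> ScenarioConfig:
    """Study-like qPCR scenario: clock genes + nuclear receptors, 3 groups, 2 tissues.

    Ground-truth acrophases follow the rhythmic profiles the study design is
    built around (per genes peaking at the end of the dark phase, bmal1a in
    antiphase, nr1d1 mid-dark); amplitudes are reduced under random feeding and
    hypothalamic rhythms are abolished under constant darkness, while hepatic
    rhythms persist with reduced amplitude (light-entrained central oscillator
    vs food-entrained liver).  Fold-scale mesors/amplitudes keep the trough
    near the calibrator level so that amplitudes exceed 1 in relative units.
    """
    hyp = [
        # gene, mesor, amplitude, acrophase_h
        ("per1a", 3.2, 2.0, 22.3),
        ("per1b", 3.4, 2.2, 23.1),
        ("per2a", 2.8, 1.6, 4.3),
        ("per3", 3.0, 1.8, 1.0),
        ("clock1a", 2.0, 0.0, 0.0),
        ("bmal1a", 3.0, 1.8, 8.8),
        ("nr1d1", 3.5, 2.3, 17.5),
    ]
    liv = [
        ("per1a", 4.0, 2.8, 22.7),
        ("per1b", 3.8, 2.6, 22.5),
        ("per2a", 2.0, 0.0, 0.0),
        ("per3", 3.4, 2.2, 0.5),
        ("clock1a", 2.8, 1.6, 5.4),
        ("bmal1a", 3.2, 2.0, 7.7),
        ("nr1d1", 4.5, 3.2, 17.5),
        ("nr1d2b", 3.0, 1.8, 0.1),
        ("ppara", 3.0, 1.8, 0.3),
        ("roraa", 2.8, 1.6, 2.9),
    ]
    flat_hyp = [(g, m, 0.0, 0.0) for g, m, _, _ in hyp]
    genes = {
        ("hypothalamus", "LD_scheduled"): _clock_truths(hyp),
        ("hypothalamus", "LD_random"): _clock_truths(hyp, amp_scale=0.6),
        ("hypothalamus", "DD_scheduled"): _clock_truths(flat_hyp),
        ("liver", "LD_scheduled"): _clock_truths(liv),
        ("liver", "LD_random"): _clock_truths(liv, amp_scale=0.6),
        ("liver", "DD_scheduled"): _clock_truths(liv, amp_scale=0.4),
    }
    return ScenarioConfig(
        design=DesignGrid(n_per_time=n_per_time),
        genes=genes,
        noise=QpcrNoiseModel(ref_sd=ref_sd, technical_sd=technical_sd),
        seed=seed,
        output_kind="ct",
        noise_scale="log2",
    )


def glucose_scenario(seed: int = 0, n_per_time: int = 7) -> ScenarioConfig:
    """Plasma-glucose-like measurement scenario (mg/dl, no qPCR layer)."""
    design = DesignGrid(tissues=("plasma",), n_per_time=n_per_time)
    genes = {
        # modest rhythm, highest shortly after the morning meal
        ("plasma", "LD_scheduled"): [
            GeneTruth(gene="glucose", mesor=55.0, amplitude=6.0,
                      acrophase_h=3.0, biological_noise_sd=6.0)
        ],
        ("plasma", "LD_random"): [
            GeneTruth(gene="glucose", mesor=55.0, amplitude=8.0,
                      acrophase_h=3.0, biological_noise_sd=6.0)
        ],
        ("plasma", "DD_scheduled"): [
            GeneTruth(gene="glucose", mesor=55.0, amplitude=8.0,
                      acrophase_h=3.0, biological_noise_sd=6.0)
        ],
    }
    return ScenarioConfig(
        design=design, genes=genes, seed=seed,
        output_kind="measurement", noise_scale="additive",
    )
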