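"""Synthetic multi-panel cytometry cohorts with known ground truth.

Real patient data for this problem is not publicly deposited, so every
pipeline stage is exercised on simulated cohorts instead.  Each panel is
modeled as a Gaussian mixture in logicle-transformed marker space
(diagonal covariance): populations are cell types with characteristic
marker expression patterns.  Per sample, population frequencies are
drawn from a Dirichlet around class- and age-adjusted baselines, events
are drawn from the mixture, a per-experiment-day batch offset is added,
and intensities are mapped back to the raw instrument scale through the
inverse logicle (scatter channels linearly), yielding FCS-writable
event matrices plus per-event ground-truth population labels.

Disease effects mirror the immunophenotype this pipeline is meant to
detect: in CVID-like samples, switched-memory B-cell populations shrink
and CD21low B cells expand, with intermediate effects for other primary
antibody deficiencies; two populations follow a monotone age trend; and
each experiment day carries its own additive channel offset so that
naive (non-day-stratified) cross-validation would look optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cytodx.fcs_io import (
    EventMatrix,
    LogicleParams,
    biexponential,
    is_scatter_channel,
    write_fcs,
)

AGE_GROUPS = tuple(range(1, 9))

# canonical expression levels on the normalized logicle scale
_NEG = 0.22
_LOW = 0.38
_MID = 0.55
_HI = 0.75
_VHI = 0.88


@dataclass
class Population:
    name: str
    mean: np.ndarray  # per-marker, transformed units
    sd: np.ndarray
    frequency: float  # baseline mixture weight

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            raise ValueError("population SDs must be positive")


@dataclass
class PanelSpec:
    name: str
    markers: list[str]
    populations: list[Population]
    concentration: float = 500.0  # Dirichlet concentration (frequency noise)
    T: float = 262144.0  # top of scale for the raw instrument units

    def __post_init__(self) -> None:
        total = sum(p.frequency for p in self.populations)
        if not np.isclose(total, 1.0):
            raise ValueError(f"baseline frequencies sum to {total}, not 1")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]


@dataclass
class EffectSpec:
    """Diagnosis, age and batch effects applied on top of a panel.

    ``frequency_multipliers``: diagnosis -> {population: multiplier}.
    ``marker_shifts``: diagnosis -> {(population, marker): shift in SD
    units}.  ``age_trend``: population -> (multiplier at age group 1,
    multiplier at group 8), interpolated linearly.  ``day_offset_sd``:
    SD of the additive per-day per-channel offset (transformed units).
    ``individual_shift_sd``: SD of each donor's own population-mean
    expression shifts (per population and marker, transformed units) —
    the inter-individual variability that dominates median-intensity
    features in real cohorts.
    """

    frequency_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    marker_shifts: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    age_trend: dict[str, tuple[float, float]] = field(default_factory=dict)
    day_offset_sd: float = 0.005
    individual_shift_sd: float = 0.01

    def __post_init__(self) -> None:
        for d in self.frequency_multipliers.values():
            if any(m <= 0 for m in d.values()):
                raise ValueError("frequency multipliers must be positive")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    panel: PanelSpec
    labels: dict[str, np.ndarray]  # per-sample per-event population names
    frequencies: pd.DataFrame  # samples x populations, drawn weights
    percentages: pd.DataFrame  # samples x populations, realized %
    mfis: pd.DataFrame  # samples x (population|marker) medians, transformed


def _pop(name, freq, markers, pattern, sd=0.05):
    mean = np.array([pattern.get(m, _NEG) for m in markers])
    return Population(name, mean, np.full(len(markers), sd), freq)


def default_panels() -> list[PanelSpec]:
    """The three study panels: PBMC, B-cell and T-cell subsets."""
    p1_markers = [
        "FSC-A", "SSC-A", "CD56", "CD3", "CD123", "CD14", "CD127",
        "CD4", "CD19", "HLA-DR", "iNKT/CD34", "CD16", "CD11c",
    ]
    m1 = p1_markers
    p1 = PanelSpec(
        name="panel1",
        markers=m1,
        populations=[
            _pop("B_cells", 0.10, m1, {"FSC-A": _MID, "SSC-A": _LOW, "CD19": _HI, "HLA-DR": _HI}),
            _pop("CD4_T_cells", 0.28, m1, {"FSC-A": _MID, "SSC-A": _LOW, "CD3": _HI, "CD4": _HI, "CD127": _HI}),
            _pop("CD4neg_T_cells", 0.18, m1, {"FSC-A": _MID, "SSC-A": _LOW, "CD3": _HI, "CD127": _MID}),
            _pop("monocytes", 0.18, m1, {"FSC-A": _HI, "SSC-A": _MID, "CD14": _HI, "HLA-DR": _HI, "CD4": _LOW, "CD11c": _MID}),
            _pop("NKT_cells", 0.03, m1, {"FSC-A": _MID, "SSC-A": _LOW, "CD3": _HI, "CD56": _MID, "iNKT/CD34": _HI}),
            _pop("NK_cells", 0.10, m1, {"FSC-A": _MID, "SSC-A": _LOW, "CD56": _HI, "CD16": _HI}),
            _pop("basophils", 0.02, m1, {"FSC-A": _LOW, "SSC-A": _LOW, "CD123": _HI}),
            _pop("pDC", 0.02, m1, {"FSC-A": _MID, "SSC-A": _LOW, "CD123": _HI, "HLA-DR": _HI}),
            _pop("cDC", 0.04, m1, {"FSC-A": _HI, "SSC-A": _MID, "CD11c": _HI, "HLA-DR": _HI}),
            _pop("other_PBMC", 0.05, m1, {"FSC-A": _MID, "SSC-A": _MID}),
        ],
    )
    m2 = ["CD21", "CD24", "CD27", "CD38", "CD138", "IgA", "IgD", "IgG", "IgM"]
    p2 = PanelSpec(
        name="panel2",
        markers=m2,
        populations=[
            _pop("naive_B", 0.55, m2, {"CD21": _HI, "CD24": _MID, "IgD": _HI, "IgM": _MID, "CD38": _MID}),
            _pop("switched_memory_B_IgG", 0.08, m2, {"CD21": _HI, "CD24": _HI, "CD27": _HI, "IgG": _HI}),
            _pop("switched_memory_B_IgA", 0.05, m2, {"CD21": _HI, "CD24": _HI, "CD27": _HI, "IgA": _HI}),
            _pop("MZ_like_B", 0.10, m2, {"CD21": _HI, "CD27": _HI, "IgD": _HI, "IgM": _HI}),
            _pop("IgD_CD27_neg_B", 0.06, m2, {"CD21": _MID, "CD24": _MID, "IgG": _MID}),
            _pop("plasmablasts", 0.02, m2, {"CD27": _VHI, "CD38": _VHI, "CD24": _NEG, "IgG": _MID}),
            _pop("transitional_B", 0.05, m2, {"CD24": _VHI, "CD38": _VHI, "CD21": _MID, "IgD": _HI, "IgM": _HI}),
            _pop("CD21low_B", 0.04, m2, {"CD21": _NEG, "CD24": _MID, "IgD": _MID, "IgM": _HI}),
            _pop("CD21neg_CD38pos_B", 0.03, m2, {"CD21": _NEG, "CD38": _HI, "IgD": _MID}),
            _pop("plasma_cells", 0.02, m2, {"CD138": _HI, "CD38": _VHI, "CD27": _HI}),
        ],
    )
    m3 = ["CCR7", "CXCR5", "CD45RO", "g/dTCR", "FoxP3", "CD278", "CD8", "CD31", "CD4"]
    p3 = PanelSpec(
        name="panel3",
        markers=m3,
        populations=[
            _pop("CD4_naive", 0.22, m3, {"CCR7": _HI, "CD4": _HI, "CD31": _MID}),
            _pop("CD4_central_memory", 0.12, m3, {"CCR7": _HI, "CD45RO": _HI, "CD4": _HI, "CD278": _MID}),
            _pop("CD4_effector_memory", 0.10, m3, {"CD45RO": _HI, "CD4": _HI, "CD278": _MID}),
            _pop("CD4_emra", 0.04, m3, {"CD4": _HI}),
            _pop("CD8_naive", 0.12, m3, {"CCR7": _HI, "CD8": _HI, "CD31": _MID}),
            _pop("CD8_central_memory", 0.06, m3, {"CCR7": _HI, "CD45RO": _HI, "CD8": _HI}),
            _pop("CD8_effector_memory", 0.08, m3, {"CD45RO": _HI, "CD8": _HI}),
            _pop("CD8_emra", 0.08, m3, {"CD8": _HI}),
            _pop("gd_T_cells", 0.05, m3, {"g/dTCR": _HI}),
            _pop("Treg", 0.04, m3, {"FoxP3": _HI, "CD4": _HI, "CD278": _MID}),
            _pop("CD31_RO_neg_CD4", 0.05, m3, {"CD31": _HI, "CD4": _HI, "CCR7": _MID}),
            _pop("CD31_RO_neg_CD8", 0.04, m3, {"CD31": _HI, "CD8": _HI, "CCR7": _MID}),
        ],
    )
    return [p1, p2, p3]


def default_effects(panel: PanelSpec) -> EffectSpec:
    """Diagnosis/age/batch effects mirroring the CVID immunophenotype."""
    if panel.name == "panel2":
        # CVID reshapes the whole memory/antibody-secreting compartment:
        # switched memory of all isotypes and plasmablasts/plasma cells
        # collapse, CD21low and transitional B cells expand, and surface
        # immunoglobulin and CD27 levels drop on the remaining memory cells
        freq = {
            "CVID": {
                "switched_memory_B_IgG": 0.5,
                "switched_memory_B_IgA": 0.5,
                "plasmablasts": 0.5,
                "plasma_cells": 0.5,
                "MZ_like_B": 0.7,
                "CD21low_B": 2.0,
                "CD21neg_CD38pos_B": 1.5,
                "transitional_B": 1.3,
            },
            "otherPAD": {
                "switched_memory_B_IgG": 0.8,
                "plasmablasts": 0.8,
                "CD21low_B": 1.3,
            },
        }
        shifts = {
            "CVID": {
                ("switched_memory_B_IgG", "CD27"): -1.0,
                ("switched_memory_B_IgA", "CD27"): -1.0,
                ("switched_memory_B_IgG", "IgG"): -1.0,
                ("switched_memory_B_IgA", "IgA"): -1.0,
                ("MZ_like_B", "IgM"): -0.8,
                ("naive_B", "IgD"): -0.5,
                ("plasma_cells", "CD138"): -0.6,
                ("CD21low_B", "CD24"): 0.8,
            },
            "otherPAD": {
                ("switched_memory_B_IgG", "IgG"): -0.5,
                ("naive_B", "IgD"): -0.3,
            },
        }
        age = {"naive_B": (1.25, 0.8), "switched_memory_B_IgG": (0.8, 1.2)}
    elif panel.name == "panel1":
        freq = {
            "CVID": {"NK_cells": 0.7, "B_cells": 0.8},
            "otherPAD": {"NK_cells": 0.85},
        }
        shifts = {}
        age = {"CD4_T_cells": (1.15, 0.9), "NK_cells": (0.85, 1.15)}
    elif panel.name == "panel3":
        freq = {
            "CVID": {"CD4_naive": 0.7, "CD8_effector_memory": 1.4},
            "otherPAD": {"CD4_naive": 0.8, "CD8_effector_memory": 1.3},
        }
        shifts = {}
        age = {"CD4_naive": (1.3, 0.75), "CD8_effector_memory": (0.8, 1.25)}
    else:
        freq, shifts, age = {}, {}, {}
    return EffectSpec(
        frequency_multipliers=freq, marker_shifts=shifts, age_trend=age
    )


def null_effects() -> EffectSpec:
    """Batch and age effects only — no diagnosis signal."""
    return EffectSpec()


def _age_multiplier(effects: EffectSpec, pop: str, age_group: int) -> float:
    if pop not in effects.age_trend:
        return 1.0
    lo, hi = effects.age_trend[pop]
    frac = (age_group - 1) / (len(AGE_GROUPS) - 1)
    return lo + (hi - lo) * frac


def generate_cohort(
    panel: PanelSpec,
    effects: EffectSpec,
    n_per_class: dict[str, int],
    n_days: int,
    n_events_per_sample: int,
    seed: int,
    out_dir=None,
) -> tuple[dict[str, EventMatrix], pd.DataFrame, CohortTruth]:
    """Simulate a cohort of raw-scale FCS samples.

    Returns ``(samples, meta, truth)``: per-sample raw event matrices
    (with a Time channel), a metadata table indexed by sample id
    (diagnosis, age_group, day, path), and the ground truth.  When
    ``out_dir`` is given each sample is also written as an FCS file.
    Deterministic for a fixed seed, including FCS bytes.
    """
    if n_days < 2:
        raise ValueError("need at least two experiment days")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    lp = LogicleParams(T=panel.T, M=4.5, W=0.5, A=0.0)
    pops = panel.populations
    base = np.array([p.frequency for p in pops])
    if np.any(base <= 0):
        raise ValueError("baseline frequencies must be strictly positive")

    # per-day additive channel offsets (batch effect), fixed per day
    day_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    day_offsets = {
        d: day_rng.normal(0.0, effects.day_offset_sd, len(panel.markers))
        for d in range(1, n_days + 1)
    }

    sample_ids, diagnoses, days_list = [], [], []
    for diag, n in n_per_class.items():
        for i in range(1, n + 1):
            sample_ids.append(f"{diag}{i:03d}")
            diagnoses.append(diag)
        # accrue each diagnosis group across acquisition days (stratified
        # scheduling, as in a prospective cohort) so no day monopolizes
        # a class
        class_days = np.tile(np.arange(1, n_days + 1), int(np.ceil(n / n_days)))[:n]
        days_list.extend(rng.permutation(class_days))
    n_samples = len(sample_ids)
    days = np.array(days_list)
    age_groups = rng.integers(1, len(AGE_GROUPS) + 1, n_samples)

    meta = pd.DataFrame(
        {
            "diagnosis": diagnoses,
            "age_group": age_groups,
            "day": days,
            "path": None,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    samples: dict[str, EventMatrix] = {}
    labels: dict[str, np.ndarray] = {}
    freq_rows, pct_rows, mfi_rows = {}, {}, {}
    channels = panel.markers + ["Time"]
    ranges = {m: panel.T for m in panel.markers}

    for sid in sample_ids:
        diag = meta.loc[sid, "diagnosis"]
        age = int(meta.loc[sid, "age_group"])
        day = int(meta.loc[sid, "day"])
        mult = np.array(
            [
                effects.frequency_multipliers.get(diag, {}).get(p.name, 1.0)
                * _age_multiplier(effects, p.name, age)
                for p in pops
            ]
        )
        adj = base * mult
        adj = adj / adj.sum()
        freqs = rng.dirichlet(panel.concentration * adj)
        counts = rng.multinomial(n_events_per_sample, freqs)

        blocks, labs = [], []
        shifts = effects.marker_shifts.get(diag, {})
        # this donor's own expression idiosyncrasies
        indiv = rng.normal(
            0.0, effects.individual_shift_sd, (len(pops), len(panel.markers))
        )
        mfi_row = {}
        for pi, (p, c) in enumerate(zip(pops, counts)):
            mean = p.mean + indiv[pi]
            for (pop_name, marker), s in shifts.items():
                if pop_name == p.name:
                    mean[panel.markers.index(marker)] += s * p.sd[
                        panel.markers.index(marker)
                    ]
            ev = rng.normal(mean, p.sd, size=(c, len(panel.markers)))
            blocks.append(ev)
            labs.extend([p.name] * c)
            for j, mk in enumerate(panel.markers):
                mfi_row[f"{p.name}|{mk}"] = (
                    float(np.median(ev[:, j])) if c else 0.0
                )
        Y = np.vstack([b for b in blocks if b.size] or [np.empty((0, len(pops[0].mean)))])
        lab_arr = np.array(labs, dtype=object)
        order = rng.permutation(Y.shape[0])
        Y = Y[order] + day_offsets[day]
        lab_arr = lab_arr[order]

        raw = np.empty_like(Y)
        for j, mk in enumerate(panel.markers):
            if is_scatter_channel(mk):
                raw[:, j] = Y[:, j] * panel.T
            else:
                raw[:, j] = biexponential(Y[:, j], lp)
        t = np.cumsum(rng.exponential(1.0, Y.shape[0]))
        values = np.column_stack([raw, t])
        E = EventMatrix(
            values=values,
            channels=channels,
            ranges={**ranges, "Time": float(t[-1]) if t.size else 1.0},
        )
        samples[sid] = E
        labels[sid] = lab_arr
        freq_rows[sid] = freqs
        pct_rows[sid] = 100.0 * counts / counts.sum()
        mfi_rows[sid] = mfi_row
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{sid}.fcs"
            write_fcs(E, path)
            meta.loc[sid, "path"] = str(path)

    pop_names = panel.population_names
    truth = CohortTruth(
        panel=panel,
        labels=labels,
        frequencies=pd.DataFrame.from_dict(
            freq_rows, orient="index", columns=pop_names
        ),
        percentages=pd.DataFrame.from_dict(
            pct_rows, orient="index", columns=pop_names
        ),
        mfis=pd.DataFrame.from_dict(mfi_rows, orient="index"),
    )
    if out_dir is not None:
        meta.to_csv(Path(out_dir) / "metadata.csv")
    return samples, meta, truth


N_MANUAL_FEATURES = 47


def attach_manual_labels(truth: CohortTruth) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Export the generator's mixture components as a manual gating.

    Returns the per-event population labels and a per-sample
    47-column manual feature table: one percentage column per
    population, padded with per-population marker MFIs (in a fixed
    deterministic order) up to exactly 47 columns — matching the size
    and spirit of a hand-gated baseline, not its exact columns.
    """
    pct = truth.percentages.add_prefix("pct_")
    n_mfi = N_MANUAL_FEATURES - pct.shape[1]
    if n_mfi < 0:
        raise ValueError("more populations than manual feature slots")
    mfi_cols = list(truth.mfis.columns)[:n_mfi]
    table = pd.concat(
        [pct, truth.mfis[mfi_cols].add_prefix("mfi_")], axis=1
    )
    assert table.shape[1] == N_MANUAL_FEATURES
    return truth.labels, table
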