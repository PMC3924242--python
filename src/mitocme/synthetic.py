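"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes, and returns the ground truth alongside the data so the
pipeline can be validated end to end without any experimental download:

* tether traces: plateau/step bead-displacement records at 5-20 kHz with
  a stage-driven zero-reference dip and i.i.d. Gaussian displacement
  noise;
* label-free quantitation (LFQ) tables: log-normal protein intensities
  over paired interphase/mitotic samples with a Gaussian null of log2
  ratios, injected outliers, condition-exclusive proteins and missing
  (zero) values;
* cell images: disc cells with an annular cortex, cytoplasmic fill,
  diffuse G-actin, transferrin puncta and uniform background;
* flow-cytometry event tables: mixtures of log-normal FL1 populations
  with sub-threshold debris.

All generators are deterministic given their spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tether import (
    EVENT_AWAY,
    EVENT_TETHER_FORMED,
    EVENT_TOWARD,
    TetherTrace,
)

__all__ = [
    "TraceGenSpec",
    "LfqGenSpec",
    "OutlierSpec",
    "ExclusiveSpec",
    "ImageGenSpec",
    "FlowGenSpec",
    "FlowPopulation",
    "gen_tether_trace",
    "gen_lfq_table",
    "gen_cell_image",
    "gen_flow_events",
    "IMAGE_CHANNELS",
]

# ---------------------------------------------------------------------------
# Tether traces

DEFAULT_EVENT_SCHEDULE: tuple[tuple[float, str], ...] = (
    (0.5, EVENT_TETHER_FORMED),
    (6.0, EVENT_TOWARD),
    (11.0, EVENT_AWAY),
)


@dataclass(frozen=True)
class TraceGenSpec:
    """Parameters of one synthetic tether-pull.

    The default schedule forms the tether at 0.5 s, moves the cell toward
    the bead at 6 s (zero reference) and away again at 11 s, so the
    plateau window is (5, 6) s and the zero-reference window is nearly
    5 s long.
    """

    sampling_rate: float = 5000.0  # Hz, 5-20 kHz in practice
    trap_stiffness: float = 0.3  # pN/nm
    true_force: float = 20.0  # pN per tether
    noise_sd: float = 10.0  # nm, displacement-domain Gaussian noise
    event_schedule: tuple[tuple[float, str], ...] = DEFAULT_EVENT_SCHEDULE
    tether_count: int = 1
    drift_offset: float = 0.0  # nm
    duration: float = 12.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.true_force < 0:
            raise ValueError("true_force must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tether_count < 1:
            raise ValueError("tether_count must be >= 1")
        times = [t for t, _ in self.event_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")


def gen_tether_trace(
    spec: TraceGenSpec,
    cell_id: str = "cell",
    experiment_id: str = "exp",
    phase: str = "interphase",
) -> tuple[TetherTrace, float]:
    """Generate a bead-displacement trace; return it with the true total
    plateau force (pN).

    While a tether is under tension the displacement is
    ``drift_offset + true_force * tether_count / trap_stiffness + noise``;
    during the toward-cell zero-reference window (and before tether
    formation) it is ``drift_offset + noise``.  A schedule lacking a
    toward/away pair is flagged in the trace metadata, not an error.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.sampling_rate * spec.duration))
    t = np.arange(n) / spec.sampling_rate

    total_force = spec.true_force * spec.tether_count
    plateau_nm = total_force / spec.trap_stiffness
    tense = np.zeros(n, dtype=bool)
    state = False
    prev = 0.0
    for et, label in spec.event_schedule:
        tense[(t >= prev) & (t < et)] = state
        if label == EVENT_TETHER_FORMED:
            state = True
        elif label == EVENT_TOWARD:
            state = False
        elif label == EVENT_AWAY:
            state = True
        prev = et
    tense[t >= prev] = state

    disp = np.full(n, spec.drift_offset)
    disp[tense] += plateau_nm
    if spec.noise_sd > 0:
        disp = disp + rng.normal(0.0, spec.noise_sd, size=n)

    labels = {label for _, label in spec.event_schedule}
    metadata = {"true_force": total_force, "tether_count": spec.tether_count}
    if EVENT_TOWARD not in labels or EVENT_AWAY not in labels:
        metadata["no_zero_reference_events"] = True

    trace = TetherTrace(
        time=t,
        displacement=disp,
        events=list(spec.event_schedule),
        stiffness=spec.trap_stiffness,
        cell_id=cell_id,
        experiment_id=experiment_id,
        phase=phase,
        metadata=metadata,
    )
    return trace, total_force


def gen_no_load_segment(
    stiffness: float,
    n_samples: int = 10_000,
    temperature: float = 298.0,
    seed: int = 0,
) -> np.ndarray:
    """Thermal positional fluctuations of a trapped, tether-free bead.

    Gaussian with variance ``kB*T / k`` (equipartition), for exercising
    the stiffness calibration.
    """
    from .tether import BOLTZMANN_PN_NM_PER_K

    rng = np.random.default_rng(seed)
    sd = math.sqrt(BOLTZMANN_PN_NM_PER_K * temperature / stiffness)
    return rng.normal(0.0, sd, size=n_samples)


# ---------------------------------------------------------------------------
# LFQ protein-group tables

CONDITIONS = ("interphase", "mitotic")


@dataclass(frozen=True)
class OutlierSpec:
    """A protein whose interphase/mitotic ratio is set, not drawn.

    ``experiments`` restricts the injected ratio to a subset of
    experiments (1-based); elsewhere the protein behaves as null.  None
    means all experiments.
    """

    protein_id: str
    true_ratio: float
    experiments: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")


@dataclass(frozen=True)
class ExclusiveSpec:
    """A protein detected in one condition only, with the stated LFQ value."""

    protein_id: str
    condition: str
    intensity: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")


@dataclass(frozen=True)
class LfqGenSpec:
    """Parameters of a synthetic protein-group quantitation table.

    Null proteins have a log2 interphase/mitotic ratio drawn from
    Normal(null_mu, null_sigma^2); the ratio multiplies the interphase
    channel of a shared per-experiment abundance, so the realised ratio
    equals the draw exactly.  ``experiment_scatter`` (log2 units) adds
    independent per-experiment deviation around the protein ratio when a
    per-experiment analysis with imperfect reproducibility is wanted.
    """

    n_proteins: int = 1000
    n_experiments: int = 4
    null_mu: float = 0.2  # log2 units
    null_sigma: float = 0.8  # log2 units
    outlier_specs: tuple[OutlierSpec, ...] = ()
    dropout_rate: float = 0.05
    exclusive_specs: tuple[ExclusiveSpec, ...] = ()
    intensity_scale: float = 1e7
    experiment_scatter: float = 0.0  # log2 units
    abundance_sigma: float = 1.0  # ln units, protein-to-protein
    load_sigma: float = 0.25  # ln units, experiment-to-experiment
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.null_sigma <= 0:
            raise ValueError("null_sigma must be > 0")
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        ids = [s.protein_id for s in self.outlier_specs] + [
            s.protein_id for s in self.exclusive_specs
        ]
        dupes = {p for p in ids if ids.count(p) > 1}
        if dupes:
            raise ValueError(f"duplicate protein_id across specs: {sorted(dupes)}")


def gen_lfq_table(spec: LfqGenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a MaxQuant-style proteinGroups table and its truth table.

    Returns
    -------
    table : DataFrame
        Columns ``Protein IDs``, ``Gene names`` and
        ``LFQ intensity <condition>_<experiment>``.
    truth : DataFrame
        Per-protein category (null / outlier / *_exclusive), true ratio
        and true log2 ratio.
    """
    rng = np.random.default_rng(spec.seed)
    E = spec.n_experiments

    rows: list[dict] = []
    truth_rows: list[dict] = []

    def _experiment_ratios(base_log2: float, scatter_mask: np.ndarray | None = None,
                           null_draws: np.ndarray | None = None) -> np.ndarray:
        r = np.full(E, base_log2)
        if scatter_mask is not None and null_draws is not None:
            r = np.where(scatter_mask, r, null_draws)
        if spec.experiment_scatter > 0:
            r = r + rng.normal(0.0, spec.experiment_scatter, size=E)
        return r

    def _emit(protein_id: str, r_exp: np.ndarray | None, category: str,
              true_ratio: float, exclusive_condition: str | None = None,
              exclusive_intensity: float = 0.0) -> None:
        base = spec.intensity_scale * rng.lognormal(0.0, spec.abundance_sigma)
        load = rng.lognormal(0.0, spec.load_sigma, size=E)
        row: dict = {"Protein IDs": protein_id, "Gene names": protein_id}
        for e in range(E):
            if exclusive_condition is None:
                assert r_exp is not None
                inter = base * load[e] * 2.0 ** r_exp[e]
                mito = base * load[e]
            else:
                val = exclusive_intensity * load[e]
                inter = val if exclusive_condition == "interphase" else 0.0
                mito = val if exclusive_condition == "mitotic" else 0.0
            row[f"LFQ intensity interphase_{e + 1}"] = inter
            row[f"LFQ intensity mitotic_{e + 1}"] = mito
        rows.append(row)
        truth_rows.append(
            {
                "protein_id": protein_id,
                "category": category,
                "true_ratio": true_ratio,
                "true_log2_ratio": math.log2(true_ratio) if true_ratio > 0 else np.nan,
            }
        )

    for ospec in spec.outlier_specs:
        r = math.log2(ospec.true_ratio)
        if ospec.experiments is None:
            r_exp = _experiment_ratios(r)
        else:
            mask = np.array([e + 1 in ospec.experiments for e in range(E)])
            nulls = rng.normal(spec.null_mu, spec.null_sigma, size=E)
            r_exp = _experiment_ratios(r, mask, nulls)
        _emit(ospec.protein_id, r_exp, "outlier", ospec.true_ratio)

    for xspec in spec.exclusive_specs:
        _emit(
            xspec.protein_id,
            None,
            f"{xspec.condition}_exclusive",
            np.nan,
            exclusive_condition=xspec.condition,
            exclusive_intensity=xspec.intensity,
        )

    for i in range(spec.n_proteins):
        r = float(rng.normal(spec.null_mu, spec.null_sigma))
        r_exp = _experiment_ratios(r)
        _emit(f"NULL{i + 1:05d}", r_exp, "null", 2.0 ** r)

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    if spec.dropout_rate > 0:
        lfq_cols = [c for c in table.columns if c.startswith("LFQ intensity")]
        values = table[lfq_cols].to_numpy()
        drop = rng.random(values.shape) < spec.dropout_rate
        values[drop] = 0.0
        table[lfq_cols] = values

    return table, truth


# ---------------------------------------------------------------------------
# Cell images

IMAGE_CHANNELS = ("f_actin", "g_actin", "tf")


@dataclass(frozen=True)
class ImageGenSpec:
    """Parameters of one synthetic equatorial cell section.

    The cell is a disc with an annular cortex of ``cortex_width`` px.
    Channel 0 (F-actin) has ``cortex_intensity`` on the ring and
    ``cytoplasm_intensity`` inside it; channel 1 (G-actin) is uniform at
    ``g_cytoplasm_intensity`` within the cell; channel 2 (transferrin) is
    background plus ``puncta_count`` spots of integrated intensity
    ``puncta_intensity`` each.  Outside the cell all channels sit at
    ``background_intensity``.
    """

    image_size: tuple[int, int] = (256, 256)
    cell_radius: float = 80.0  # px
    cortex_width: float = 24.0  # px, matches the default border-ring ROI
    cortex_intensity: float = 200.0
    cytoplasm_intensity: float = 100.0
    background_intensity: float = 50.0
    g_cytoplasm_intensity: float = 120.0
    puncta_count: int = 30
    puncta_intensity: float = 500.0  # integrated per punctum
    noise_sd: float = 0.0
    center: tuple[float, float] | None = None  # (row, col)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortex_width < 1:
            raise ValueError("cortex_width must be >= 1 px")
        if self.cortex_width >= self.cell_radius:
            raise ValueError("cortex_width must be smaller than cell_radius")
        for v in (self.cortex_intensity, self.cytoplasm_intensity,
                  self.background_intensity, self.g_cytoplasm_intensity):
            if v < 0:
                raise ValueError("intensities must be >= 0")
        if self.puncta_count < 0:
            raise ValueError("puncta_count must be >= 0")
        cy, cx = self.resolved_center
        h, w = self.image_size
        if (cy - self.cell_radius < 0 or cy + self.cell_radius >= h
                or cx - self.cell_radius < 0 or cx + self.cell_radius >= w):
            raise ValueError("cell does not fit within the image")

    @property
    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.image_size[0] / 2.0, self.image_size[1] / 2.0)


def _punctum_kernel(sigma: float = 1.5, radius: int = 4) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return k / k.sum()


def gen_cell_image(spec: ImageGenSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate a 3-channel image stack, its cell mask, and ground truth.

    Returns
    -------
    stack : float array, shape (3, H, W)
        Channels in ``IMAGE_CHANNELS`` order (F-actin, G-actin,
        transferrin).
    mask : bool array, shape (H, W)
        True inside the cell.
    truth : dict
        ``f_actin_ratio`` (cortex/cytoplasm, background-subtracted),
        ``g_actin_mean`` (background-subtracted), ``tf_total`` (summed
        punctum signal), all recorded before noise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = spec.resolved_center
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(yy - cy, xx - cx)
    mask = rho <= spec.cell_radius
    cortex = mask & (rho > spec.cell_radius - spec.cortex_width)

    bg = float(spec.background_intensity)
    f = np.full((h, w), bg, dtype=float)
    f[mask] = spec.cytoplasm_intensity
    f[cortex] = spec.cortex_intensity

    g = np.full((h, w), bg, dtype=float)
    g[mask] = spec.g_cytoplasm_intensity

    tf = np.full((h, w), bg, dtype=float)
    kernel = _punctum_kernel()
    kr = kernel.shape[0] // 2
    inner = spec.cell_radius - spec.cortex_width - kr - 1
    for _ in range(spec.puncta_count):
        theta = rng.uniform(0, 2 * math.pi)
        r = inner * math.sqrt(rng.uniform())
        py = int(round(cy + r * math.sin(theta)))
        px = int(round(cx + r * math.cos(theta)))
        tf[py - kr:py + kr + 1, px - kr:px + kr + 1] += spec.puncta_intensity * kernel

    stack = np.stack([f, g, tf])
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)

    if spec.cortex_intensity == spec.cytoplasm_intensity:
        ratio = 1.0  # uniform field
    elif spec.cytoplasm_intensity == bg:
        ratio = float("nan")
    else:
        ratio = (spec.cortex_intensity - bg) / (spec.cytoplasm_intensity - bg)
    truth = {
        "f_actin_ratio": ratio,
        "g_actin_mean": spec.g_cytoplasm_intensity - bg,
        "tf_total": float(spec.puncta_count * spec.puncta_intensity),
    }
    return stack, mask, truth


# ---------------------------------------------------------------------------
# Flow-cytometry event tables


@dataclass(frozen=True)
class FlowPopulation:
    """One cell population: FSC Gaussian, FL1 log-normal."""

    fraction: float
    fsc_mean: float = 500.0
    fsc_sd: float = 80.0
    fl1_log_mean: float = math.log(100.0)
    fl1_log_sd: float = 0.5
    name: str = ""


@dataclass(frozen=True)
class FlowGenSpec:
    """Parameters of a synthetic flow-cytometry sample.

    ``debris_fraction`` of all events are sub-cellular particles with FSC
    strictly below ``fsc_gate``; the remaining events are split among
    ``population_params`` (fractions summing to 1).
    """

    n_events: int = 10_000
    population_params: tuple[FlowPopulation, ...] = (FlowPopulation(1.0, name="cells"),)
    debris_fraction: float = 0.0
    fsc_gate: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if not (0 <= self.debris_fraction < 1):
            raise ValueError("debris_fraction must lie in [0, 1)")
        total = sum(p.fraction for p in self.population_params)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"population fractions must sum to 1, got {total}")


def gen_flow_events(spec: FlowGenSpec) -> tuple[pd.DataFrame, dict]:
    """Generate an FSC/SSC/FL1 event table with per-population truth.

    Truth records each population's FL1 geometric mean
    (``exp(fl1_log_mean)``), realised event counts, per-event population
    labels, and the exact number of events with FSC below the gate.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    n_debris = int(round(spec.debris_fraction * n))
    n_cells = n - n_debris

    # deterministic largest-remainder allocation of cells to populations
    raw = [p.fraction * n_cells for p in spec.population_params]
    counts = [int(math.floor(x)) for x in raw]
    rem = n_cells - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1

    fsc_parts, ssc_parts, fl1_parts, labels = [], [], [], []
    for i, (pop, c) in enumerate(zip(spec.population_params, counts)):
        if c == 0:
            continue
        fsc_parts.append(rng.normal(pop.fsc_mean, pop.fsc_sd, size=c))
        ssc_parts.append(np.abs(rng.normal(0.6 * pop.fsc_mean, pop.fsc_sd, size=c)))
        fl1_parts.append(rng.lognormal(pop.fl1_log_mean, pop.fl1_log_sd, size=c))
        labels.extend([pop.name or f"pop{i}"] * c)
    if n_debris:
        fsc_parts.append(rng.uniform(0.05 * spec.fsc_gate, 0.95 * spec.fsc_gate, size=n_debris))
        ssc_parts.append(np.abs(rng.normal(60.0, 25.0, size=n_debris)))
        fl1_parts.append(rng.lognormal(math.log(5.0), 0.6, size=n_debris))
        labels.extend(["debris"] * n_debris)

    fsc = np.concatenate(fsc_parts)
    ssc = np.concatenate(ssc_parts)
    fl1 = np.concatenate(fl1_parts)
    label_arr = np.array(labels)
    perm = rng.permutation(n)
    events = pd.DataFrame({"FSC": fsc[perm], "SSC": ssc[perm], "FL1": fl1[perm]})
    label_arr = label_arr[perm]

    truth = {
        "populations": {
            (pop.name or f"pop{i}"): {
                "fl1_geometric_mean": math.exp(pop.fl1_log_mean),
                "n": counts[i],
            }
            for i, pop in enumerate(spec.population_params)
        },
        "n_debris": n_debris,
        "n_below_gate": int((events["FSC"] < spec.fsc_gate).sum()),
        "population_labels": label_arr,
    }
    return events, truth


def replace_spec(spec, **kwargs):
    """Convenience: dataclasses.replace that works for any generator spec."""
    return replace(spec, **kwargs)
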