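"""Synthetic GC×GC compound datasets with known ground truth.

The generator emulates the statistical structure of a large, chemically
diverse GC×GC compound table (n-alkanes, PEGs, FAMEs, PCBs and other
halogenated compounds, plus a heterogeneous remainder) so that every stage
of the pipeline — indexing, splitting, PLS, federation, evaluation — is
testable without measured data.

Generative model (per compound, three latents):

* volatility v (an effective carbon number): ¹tR = t1(C8 anchor) +
  b·(v − 8) + group offset, clipped to the run; n-alkanes have v = n
  exactly, so the alkane reference series is linear and LRI(C_n) = 100·n.
* elution temperature T_e = 35 + 5·(¹tR/60 − 0.2) °C, capped at the
  310 °C final temperature (35 °C start, 0.2 min hold, 5 °C/min ramp).
* polarity p and polarizability z drive the second dimension through the
  index contribution u = (c·p + d·(z − z_ref) + group offset) ·
  exp(−κ·(T_e − T_ref)/100); ²tR = base(¹tR) + gap(¹tR)·u/100 where base
  and gap are the n-alkane baseline and the PEG-line offset. Alkanes
  (p = 0, z = z_ref) sit exactly on the baseline (u = 0) and PEG oligomers
  exactly on the PEG line (u = 100); halogenated groups carry a positive
  offset (long second-dimension retention even when non-polar).

Descriptors are noisy linear images of the standardized latents (plus
retention-irrelevant columns driven by nuisance latents, so descriptor
pruning has work to do) together with
named columns — a boiling-point proxy, logK_OW, molecular weight and
Abraham-style E, S, A, B, L — so the benchmark models and the federation
property sets can run. Measured responses are truth plus Gaussian noise;
the retention indices (LRI, PEG-²I) are then *derived* from the noisy
times with the indexing module, exactly as for real data. Homologous-series
(group 3) compounds get strongly reduced response noise and a
first-dimension group offset, making them nearly perfectly linear in chain
length but systematically displaced from the pooled trend — the structure
that makes local models pay off. The fluorinated group gets inflated
second-dimension noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .indexing import (
    ReferenceSeries,
    compute_lri,
    compute_peg_2i,
    fit_reference_lines,
)
from .io import CompoundRecord

__all__ = ["SyntheticConfig", "TruthRecord", "true_retention_model", "generate_dataset",
           "PROPERTY_NAMES"]

#: named physico-chemical property columns (knowledge-base similarity set)
PROPERTY_NAMES = ["bp", "logKow", "MW", "E", "S", "A", "B", "L"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions.

    Retention-model constants follow a 35 °C → 310 °C, 5 °C/min
    temperature program with a 0.2 min initial hold and 12 min final hold;
    alkane anchors C8–C30 span roughly 420–3300 s in the first dimension
    and the PEG/baseline geometry keeps second-dimension times within the
    5 s modulation scale.
    """

    seed: int
    n_compounds: int = 859
    n_base_descriptors: int = 150
    noise_descriptor_frac: float = 0.30
    descriptor_noise_sd: float = 0.1
    sigma_t1: float = 30.0  # s
    sigma_t2: float = 0.12  # s
    #: weights for groups 1 (fluorinated), 2 (chlorinated/brominated),
    #: 3 (long carbon chain), 4 (remainder), applied to non-series compounds
    group_weights: tuple = (0.07, 0.27, 0.15, 0.51)
    pcb_fraction: float = 0.15
    # temperature program (°C, °C/min, min)
    temp_start: float = 35.0
    temp_ramp: float = 5.0
    temp_hold0_min: float = 0.2
    temp_final: float = 310.0
    final_hold_min: float = 12.0
    # first dimension: alkane anchors and volatility effect
    alkane_c_min: int = 8
    alkane_c_max: int = 30
    t1_c8: float = 420.0  # s, C8 anchor
    t1_per_carbon: float = 131.0  # s per carbon number
    # second dimension: reference-line geometry (s vs s)
    base_intercept: float = 1.55
    base_slope: float = 5e-5
    peg_intercept: float = 3.30
    peg_slope: float = 1.5e-4
    # index contribution: u = (c·pol + d·(polz − polz_ref) + offset)·atten
    pol_coef: float = 60.0
    polz_coef: float = 30.0
    polz_ref: float = 0.5
    temp_atten: float = 0.25
    temp_ref: float = 150.0
    peg_eo_min: int = 3
    peg_eo_max: int = 10
    #: unmodeled group structure: first-dimension offsets (s) and
    #: second-dimension index offsets, by group label
    group_t1_offsets: dict = field(default_factory=lambda: {3: -45.0})
    group_index_offsets: dict = field(default_factory=lambda: {1: 12.0, 2: 8.0})
    group3_noise_scale: float = 0.05
    fluor_t2_noise_scale: float = 2.0

    def __post_init__(self):
        if abs(sum(self.group_weights) - 1.0) > 1e-9:
            raise ValueError("group weights must sum to 1")
        if self.sigma_t1 < 0 or self.sigma_t2 < 0:
            raise ValueError("noise SDs must be nonnegative")

    def noise_free(self) -> "SyntheticConfig":
        """Copy with all noise and unmodeled group structure removed."""
        return replace(
            self,
            sigma_t1=0.0,
            sigma_t2=0.0,
            descriptor_noise_sd=0.0,
            group_t1_offsets={},
            group_index_offsets={},
        )


@dataclass
class TruthRecord:
    """Ground truth for one generated compound (recovery tests)."""

    compound_id: str
    volatility: float
    polarity: float
    polarizability: float
    group: int
    series: str  # alkane | peg | fame | none
    t1_true: float
    t2_true: float
    lri_true: float
    peg2i_true: float


def _elution_temperature(t1: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    te = cfg.temp_start + cfg.temp_ramp * (t1 / 60.0 - cfg.temp_hold0_min)
    return np.minimum(te, cfg.temp_final)


def _run_end(cfg: SyntheticConfig) -> float:
    ramp_min = (cfg.temp_final - cfg.temp_start) / cfg.temp_ramp
    return 60.0 * (cfg.temp_hold0_min + ramp_min + cfg.final_hold_min)


def true_retention_model(
    volatility: np.ndarray,
    polarity: np.ndarray,
    polarizability: np.ndarray,
    group: np.ndarray,
    cfg: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (¹tR, ²tR) for arrays of latents and group labels."""
    v = np.asarray(volatility, dtype=float)
    p = np.asarray(polarity, dtype=float)
    z = np.asarray(polarizability, dtype=float)
    g = np.asarray(group)

    t1 = cfg.t1_c8 + cfg.t1_per_carbon * (v - cfg.alkane_c_min)
    t1 = t1 + np.array([cfg.group_t1_offsets.get(int(gi), 0.0) for gi in np.atleast_1d(g)])
    t1 = np.clip(t1, 60.0, _run_end(cfg))

    te = _elution_temperature(t1, cfg)
    atten = np.exp(-cfg.temp_atten * (te - cfg.temp_ref) / 100.0)
    off = np.array([cfg.group_index_offsets.get(int(gi), 0.0) for gi in np.atleast_1d(g)])
    u = (cfg.pol_coef * p + cfg.polz_coef * (z - cfg.polz_ref) + off) * atten

    base = cfg.base_intercept + cfg.base_slope * t1
    gap = (cfg.peg_intercept + cfg.peg_slope * t1) - base
    t2 = base + gap * u / 100.0
    return t1, t2


def _reference_series(cfg: SyntheticConfig) -> ReferenceSeries:
    alkanes = []
    alkane_t2 = []
    for n in range(cfg.alkane_c_min, cfg.alkane_c_max + 1):
        t1 = cfg.t1_c8 + cfg.t1_per_carbon * (n - cfg.alkane_c_min)
        alkanes.append((n, t1))
        alkane_t2.append((t1, cfg.base_intercept + cfg.base_slope * t1))
    pegs = []
    for k in range(cfg.peg_eo_min, cfg.peg_eo_max + 1):
        v = 6.0 + 1.2 * k
        t1 = cfg.t1_c8 + cfg.t1_per_carbon * (v - cfg.alkane_c_min)
        t2 = cfg.peg_intercept + cfg.peg_slope * t1
        pegs.append((k, t1, t2))
    return ReferenceSeries(alkanes=alkanes, pegs=pegs, alkane_t2=alkane_t2)


def _peg_polarity(t1: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Polarity that puts a compound exactly on the PEG line (u = 100)."""
    te = _elution_temperature(t1, cfg)
    atten = np.exp(-cfg.temp_atten * (te - cfg.temp_ref) / 100.0)
    return 100.0 / (cfg.pol_coef * atten)


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[CompoundRecord], DescriptorTable, ReferenceSeries, list[TruthRecord]]:
    """Generate compounds, descriptors, reference standards and ground truth.

    The homologous reference families (n-alkanes C8–C30 and PEG-3…PEG-10)
    are always present as dataset compounds; the remaining compounds are
    drawn from the four groups by the configured weights. Bit-reproducible
    given the seed.
    """
    if cfg.n_compounds < 50:
        warnings.warn("fewer than 50 compounds: set splitting becomes degenerate")
    rng = np.random.default_rng(cfg.seed)
    series = _reference_series(cfg)
    lines = fit_reference_lines(series)

    n_alk = cfg.alkane_c_max - cfg.alkane_c_min + 1
    n_peg = cfg.peg_eo_max - cfg.peg_eo_min + 1
    n_series = n_alk + n_peg
    if cfg.n_compounds <= n_series:
        raise ValueError(f"n_compounds must exceed {n_series} (the reference families)")
    n_rest = cfg.n_compounds - n_series

    # --- latents and groups ----------------------------------------------
    v = np.empty(cfg.n_compounds)
    pol = np.empty(cfg.n_compounds)
    polz = np.empty(cfg.n_compounds)
    group = np.empty(cfg.n_compounds, dtype=int)
    series_tag = np.array(["none"] * cfg.n_compounds, dtype=object)
    names = np.empty(cfg.n_compounds, dtype=object)

    i = 0
    for n in range(cfg.alkane_c_min, cfg.alkane_c_max + 1):
        v[i], pol[i], polz[i], group[i] = n, 0.0, cfg.polz_ref, 3
        series_tag[i], names[i] = "alkane", f"n-alkane C{n}"
        i += 1
    peg_idx = slice(i, i + n_peg)
    for k in range(cfg.peg_eo_min, cfg.peg_eo_max + 1):
        v[i], polz[i], group[i] = 6.0 + 1.2 * k, cfg.polz_ref, 3
        pol[i] = np.nan  # set from the PEG-line condition below
        series_tag[i], names[i] = "peg", f"PEG-{k}"
        i += 1

    g_rest = rng.choice([1, 2, 3, 4], size=n_rest, p=cfg.group_weights)
    for g in g_rest:
        group[i] = g
        if g == 3:  # further homologous members (FAME-like)
            v[i] = rng.uniform(10.0, 26.0)
            pol[i] = 0.7
            polz[i] = cfg.polz_ref + 0.05
            series_tag[i], names[i] = "fame", f"FAME-like {i}"
        else:
            v[i] = np.clip(rng.normal(16.0, 4.5), 6.5, 26.5)
            if g == 1:
                pol[i] = min(rng.gamma(1.5, 0.5), 2.5)
                polz[i] = max(rng.normal(0.40, 0.15), 0.05)
                names[i] = f"fluorinated {i}"
            elif g == 2:
                pol[i] = min(rng.gamma(2.0, 0.5), 2.5)
                polz[i] = max(rng.normal(0.75, 0.20), 0.05)
                names[i] = f"halogenated {i}"
            else:
                pol[i] = min(rng.gamma(2.0, 0.8), 3.0)
                polz[i] = max(rng.normal(0.55, 0.20), 0.05)
                names[i] = f"compound {i}"
        i += 1

    # PEG polarity from the on-line condition (needs t1 of the PEG members)
    t1_peg = cfg.t1_c8 + cfg.t1_per_carbon * (v[peg_idx] - cfg.alkane_c_min)
    t1_peg += cfg.group_t1_offsets.get(3, 0.0)
    pol[peg_idx] = _peg_polarity(t1_peg, cfg)
    # the group-3 index offset (if any) would push PEGs off their own line;
    # compensate so they stay exact anchors
    if cfg.group_index_offsets.get(3):
        pol[peg_idx] -= cfg.group_index_offsets[3] / cfg.pol_coef

    ids = np.array([f"cpd{j:04d}" for j in range(cfg.n_compounds)], dtype=object)

    # PCB congeners: a subset of group 2 with chlorination levels
    chlorination = np.full(cfg.n_compounds, -1, dtype=int)
    g2_idx = np.where(group == 2)[0]
    n_pcb = min(int(round(cfg.pcb_fraction * cfg.n_compounds)), g2_idx.size)
    pcb_idx = rng.choice(g2_idx, size=n_pcb, replace=False)
    if n_pcb:
        chlorination[pcb_idx] = rng.integers(1, 11, size=n_pcb)
        for j in np.sort(pcb_idx):
            names[j] = f"PCB congener {j} (Cl{chlorination[j]})"

    # --- responses ---------------------------------------------------------
    t1_true, t2_true = true_retention_model(v, pol, polz, group, cfg)
    noise_scale = np.ones(cfg.n_compounds)
    noise_scale[group == 3] = cfg.group3_noise_scale
    t2_noise_scale = noise_scale.copy()
    t2_noise_scale[group == 1] = cfg.fluor_t2_noise_scale
    t1_obs = t1_true + rng.normal(0.0, 1.0, cfg.n_compounds) * cfg.sigma_t1 * noise_scale
    t2_obs = t2_true + rng.normal(0.0, 1.0, cfg.n_compounds) * cfg.sigma_t2 * t2_noise_scale
    t1_obs = np.clip(t1_obs, 60.0, _run_end(cfg))

    lri_obs = np.array([compute_lri(t, series).value for t in t1_obs])
    peg2i_obs = np.array(
        [compute_peg_2i(a, b, lines).value for a, b in zip(t1_obs, t2_obs)]
    )
    lri_true = np.array([compute_lri(t, series).value for t in t1_true])
    peg2i_true = np.array(
        [compute_peg_2i(a, b, lines).value for a, b in zip(t1_true, t2_true)]
    )

    # --- descriptors -------------------------------------------------------
    vz = (v - 17.0) / 5.0
    pz = (pol - 1.2) / 0.9
    qz = (polz - 0.55) / 0.25
    L3 = np.column_stack([vz, pz, qz])

    # homologous-series members are regular in descriptor space too: their
    # descriptors are smooth functions of chain length, so their descriptor
    # noise is damped along with their response noise
    row_scale = np.where(group == 3, cfg.group3_noise_scale, 1.0)

    def noisy(signal, rel=1.0):
        return signal + rng.normal(0.0, 1.0, cfg.n_compounds) * (
            cfg.descriptor_noise_sd * rel * row_scale
        )

    desc = {
        "bp": noisy(vz),  # boiling-point proxy (volatility image)
        "logKow": noisy(0.85 * vz - 0.5 * pz),
        "MW": np.maximum(
            72.0
            + 14.0 * v
            + rng.normal(0.0, 1.0, cfg.n_compounds)
            * 30.0 * cfg.descriptor_noise_sd * row_scale,
            20.0,
        ),
        "E": noisy(0.9 * qz + 0.1 * pz),
        "S": noisy(0.9 * pz + 0.2 * qz),  # polarity/polarizability
        "A": noisy(0.4 * pz),
        "B": noisy(0.6 * pz),
        "L": noisy(0.9 * vz + 0.15 * qz),  # gas–hexadecane partitioning
    }
    n_irr = int(round(cfg.noise_descriptor_frac * cfg.n_base_descriptors))
    n_info = cfg.n_base_descriptors - len(desc) - n_irr
    loadings = rng.normal(0.0, 1.0, size=(n_info, 3))
    for j in range(n_info):
        desc[f"d{j:03d}"] = noisy(L3 @ loadings[j])
    # retention-irrelevant descriptors: exact images of three nuisance
    # structural latents (not per-compound noise), so pruning has work to do
    # while descriptors remain deterministic functions of structure
    nuisance = rng.normal(0.0, 1.0, size=(cfg.n_compounds, 3))
    irr_loadings = rng.normal(0.0, 1.0, size=(n_irr, 3))
    for j in range(n_irr):
        desc[f"irr{j:03d}"] = noisy(nuisance @ irr_loadings[j])

    table = DescriptorTable(pd.DataFrame(desc, index=pd.Index(ids, name="compound_id")))

    records, truth = [], []
    for j in range(cfg.n_compounds):
        records.append(
            CompoundRecord(
                compound_id=str(ids[j]),
                name=str(names[j]),
                group=int(group[j]),
                chlorination_level=int(chlorination[j]) if chlorination[j] > 0 else None,
                t1r=float(t1_obs[j]),
                t2r=float(t2_obs[j]),
                lri=float(lri_obs[j]),
                peg2i=float(peg2i_obs[j]),
            )
        )
        truth.append(
            TruthRecord(
                compound_id=str(ids[j]),
                volatility=float(v[j]),
                polarity=float(pol[j]),
                polarizability=float(polz[j]),
                group=int(group[j]),
                series=str(series_tag[j]),
                t1_true=float(t1_true[j]),
                t2_true=float(t2_true[j]),
                lri_true=float(lri_true[j]),
                peg2i_true=float(peg2i_true[j]),
            )
        )
    return records, table, series, truth


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth]).set_index("compound_id")
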