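"""Synthetic splicing-array screens with known ground truth.

Emulates a cassette-exon RT-PCR screen read out by microfluidic capillary
electrophoresis: a catalog of events with two expected amplicon sizes in
the 150–700 bp resolvable window, a planted truth table of baseline ψ and
signed knockdown effects, and per-sample data as either synthetic
electropherogram traces or pre-quantified peak tables.

The generative model, in the order the screen produces data:

* Each event has an inclusion and an exclusion amplicon whose size
  difference is the alternative-region length (>= 20 bp by default so the
  instrument can resolve them).
* Effects are planted on the ψ scale.  A true target has one signed effect
  per responsive cell line, identical in sign across lines (direction is a
  property of the event, matching how regulated exons behave under
  knockdown of a single factor).  The per-siRNA realized shift scales with
  that transfection's knockdown fraction, normalized within each cell line
  by the stronger of its two siRNAs — so the stronger knockdown expresses
  the full planted effect and the weaker one a proportional fraction.
* A small fraction of true targets respond with opposite signs in the two
  siRNAs ("discordant"; e.g. off-target effects); the concordance rule must
  veto these downstream.
* Molar amounts are back-computed from ψ (inclusion = ψ/100 of a fixed
  total), multiplied by lognormal technical noise (CV ``amount_cv``), and
  rendered either directly as a peak table or as Gaussian peaks on a trace
  with mass-proportional amplitude, a shared per-well multiplicative sizing
  error, and additive Gaussian baseline noise.

The default knockdown-fraction table reproduces the five cancer cell lines
of the screen this simulator models (two siRNA transfections each,
immunoblot-quantified protein knockdown at 96 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .electropherogram import SizeCalibration, Trace
from .psi import MOCK, SIRNAS

__all__ = [
    "AseDefinition",
    "NoiseParams",
    "ZERO_NOISE",
    "TruthTable",
    "Sample",
    "DEFAULT_KD_TABLE",
    "DEFAULT_CELL_LINES",
    "default_ladder",
    "smn_exon7_fixture",
    "generate_ase_catalog",
    "generate_truth",
    "generate_samples",
    "synthesize_trace",
    "simulate_peak_table",
    "catalog_to_frame",
    "frame_to_catalog",
]

SIZE_MIN_BP = 150
SIZE_MAX_BP = 700
MIN_ALT_REGION_BP = 20


@dataclass(frozen=True)
class AseDefinition:
    """One alternative splicing event: two expected amplicon sizes.

    The inclusion amplicon carries the alternative exon, so it is the
    longer product for a cassette exon; the size difference is the length
    of the alternative region in bp.
    """

    ase_id: str
    gene: str
    size_inclusion_bp: int
    size_exclusion_bp: int
    inclusion_is_long: bool = True

    def __post_init__(self) -> None:
        short, long_ = (
            (self.size_exclusion_bp, self.size_inclusion_bp)
            if self.inclusion_is_long
            else (self.size_inclusion_bp, self.size_exclusion_bp)
        )
        if not (SIZE_MIN_BP <= short < long_ <= SIZE_MAX_BP):
            raise ValueError(
                f"{self.ase_id}: amplicon sizes {short}/{long_} outside "
                f"[{SIZE_MIN_BP}, {SIZE_MAX_BP}] bp or mis-ordered"
            )

    @property
    def alt_region_bp(self) -> int:
        return abs(self.size_inclusion_bp - self.size_exclusion_bp)


def smn_exon7_fixture() -> AseDefinition:
    """The SMN exon 7 cassette event used as a fixed catalog fixture.

    The alternative exon is 54 nt, so the inclusion amplicon runs 54 bp
    longer than the exclusion amplicon; the flanking amplicon length (276
    bp for the exclusion product) is a simulator choice.
    """
    return AseDefinition(
        ase_id="SMN-ex7", gene="SMN", size_inclusion_bp=330, size_exclusion_bp=276
    )


#: protein knockdown fraction per (cell line, siRNA transfection), 96 h
DEFAULT_KD_TABLE = pd.DataFrame(
    [
        ("MCF-7", "siRNA1", 0.67),
        ("MCF-7", "siRNA2", 0.60),
        ("MDA-MB-231", "siRNA1", 0.53),
        ("MDA-MB-231", "siRNA2", 0.80),
        ("OVCAR-3", "siRNA1", 0.55),
        ("OVCAR-3", "siRNA2", 0.80),
        ("PC-3", "siRNA1", 0.67),
        ("PC-3", "siRNA2", 0.90),
        ("SKOV-3", "siRNA1", 0.80),
        ("SKOV-3", "siRNA2", 0.93),
    ],
    columns=["cell_line", "sirna", "kd_fraction"],
)

DEFAULT_CELL_LINES = tuple(DEFAULT_KD_TABLE["cell_line"].unique())


def default_ladder() -> SizeCalibration:
    """Sizing ladder covering 50–1000 bp, log-linear in migration time."""
    sizes = np.array([50, 100, 150, 200, 300, 400, 500, 700, 850, 1000], float)
    times = 12.0 * np.log10(sizes)
    return SizeCalibration(times=times, sizes_bp=sizes)


def generate_ase_catalog(
    n_ases: int,
    seed: int,
    duplicate_gene_fraction: float = 4 / 96,
    min_alt_region_bp: int = MIN_ALT_REGION_BP,
    max_alt_region_bp: int = 250,
    min_rel_gap: float = 0.12,
) -> list[AseDefinition]:
    """Random event catalog with resolvable amplicon size pairs.

    ``duplicate_gene_fraction`` of the events re-use an earlier event's
    gene (a screen of 96 events can cover 92 genes), so gene-level and
    event-level universes differ downstream.  The two amplicons of an
    event differ by at least ``min_alt_region_bp`` *and* by a relative gap
    of ``min_rel_gap``, keeping every pair discriminable at the default
    10% size-matching tolerance.  Deterministic in ``seed``.
    """
    if n_ases <= 0:
        raise ValueError("n_ases must be >= 1")
    rng = np.random.default_rng(seed)
    n_dup = int(round(duplicate_gene_fraction * n_ases)) if n_ases > 1 else 0
    max_exclusion = int(SIZE_MAX_BP / (1 + min_rel_gap))
    catalog: list[AseDefinition] = []
    for i in range(n_ases):
        exclusion = int(rng.integers(SIZE_MIN_BP, max_exclusion + 1))
        alt_lo = max(min_alt_region_bp, int(np.ceil(min_rel_gap * exclusion)))
        alt_hi = min(max_alt_region_bp, SIZE_MAX_BP - exclusion)
        alt = int(rng.integers(alt_lo, alt_hi + 1))
        gene = f"GENE{i + 1:04d}"
        catalog.append(
            AseDefinition(
                ase_id=f"ASE{i + 1:04d}",
                gene=gene,
                size_inclusion_bp=exclusion + alt,
                size_exclusion_bp=exclusion,
            )
        )
    if n_dup > 0:
        # late events adopt an early event's gene (second event in same gene)
        donors = rng.choice(n_ases - n_dup, size=n_dup, replace=False)
        for j, donor in enumerate(donors):
            k = n_ases - n_dup + j
            catalog[k] = AseDefinition(
                ase_id=catalog[k].ase_id,
                gene=catalog[donor].gene,
                size_inclusion_bp=catalog[k].size_inclusion_bp,
                size_exclusion_bp=catalog[k].size_exclusion_bp,
            )
    return catalog


def catalog_to_frame(catalog: Sequence[AseDefinition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.ase_id, a.gene, a.size_inclusion_bp, a.size_exclusion_bp, a.inclusion_is_long)
            for a in catalog
        ],
        columns=["ase_id", "gene", "size_inclusion_bp", "size_exclusion_bp", "inclusion_is_long"],
    )


def frame_to_catalog(df: pd.DataFrame) -> list[AseDefinition]:
    return [
        AseDefinition(
            ase_id=str(r.ase_id),
            gene=str(r.gene),
            size_inclusion_bp=int(r.size_inclusion_bp),
            size_exclusion_bp=int(r.size_exclusion_bp),
            inclusion_is_long=bool(r.inclusion_is_long),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class TruthTable:
    """Planted ground truth: baselines, signed effects, knockdown fractions.

    ``effects`` has one row per (ase_id, cell_line) with baseline_psi,
    effect_dpsi (0 for nulls / non-responsive lines) and a per-event
    discordant flag.  ``kd`` has kd_fraction per (cell_line, sirna).
    """

    effects: pd.DataFrame
    kd: pd.DataFrame
    threshold_hint: float = 8.0
    _kd_lookup: dict = field(init=False, repr=False)
    _eff_lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._kd_lookup = self.kd.set_index(["cell_line", "sirna"])["kd_fraction"].to_dict()
        self._eff_lookup = {
            (r.ase_id, r.cell_line): (r.baseline_psi, r.effect_dpsi, r.discordant)
            for r in self.effects.itertuples(index=False)
        }

    def kd_fraction(self, cell_line: str, sirna: str) -> float:
        return self._kd_lookup[(cell_line, sirna)]

    def realized_effect(self, ase_id: str, cell_line: str, sirna: str) -> float:
        """Signed Δψ this siRNA actually produces, before clamping.

        Scaled by kd_fraction / max(kd_fraction over the cell line's
        siRNAs); sign flipped for siRNA2 of a discordant event.
        """
        baseline, effect, discordant = self._eff_lookup[(ase_id, cell_line)]
        kds = [self._kd_lookup[(cell_line, s)] for s in SIRNAS]
        scale = self._kd_lookup[(cell_line, sirna)] / max(kds)
        realized = effect * scale
        if discordant and sirna == SIRNAS[1]:
            realized = -realized
        return realized

    def true_psi(self, ase_id: str, cell_line: str, condition: str) -> float:
        """Noise-free ψ of a sample, clamped to [0, 100]."""
        baseline, _, _ = self._eff_lookup[(ase_id, cell_line)]
        if condition == MOCK:
            return baseline
        return float(np.clip(baseline + self.realized_effect(ase_id, cell_line, condition), 0, 100))

    def expected_calls(self, threshold: float = 8.0, lenient: bool = False) -> pd.DataFrame:
        """Ground-truth change calls implied by the planted (clamped) shifts."""
        from .psi import call_change

        rows = []
        for (ase_id, cell_line), (baseline, _, _) in self._eff_lookup.items():
            d = {
                s: self.true_psi(ase_id, cell_line, s) - baseline for s in SIRNAS
            }
            changed, direction, _ = call_change(
                d[SIRNAS[0]], d[SIRNAS[1]], threshold=threshold, lenient=lenient
            )
            rows.append(
                {
                    "ase_id": ase_id,
                    "cell_line": cell_line,
                    "changed": changed,
                    "direction": direction,
                    "dpsi1": d[SIRNAS[0]],
                    "dpsi2": d[SIRNAS[1]],
                }
            )
        return pd.DataFrame(rows).sort_values(["ase_id", "cell_line"]).reset_index(drop=True)


def generate_truth(
    catalog: Sequence[AseDefinition],
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES,
    prop_null: float = 0.6,
    effect_mean_abs: float = 20.0,
    effect_sd: float = 6.0,
    kd_table: Optional[pd.DataFrame] = None,
    discordant_rate: float = 0.05,
    response_rate: float = 0.5,
    prob_inclusion: float = 0.68,
    seed: int = 0,
) -> TruthTable:
    """Plant baselines and signed knockdown effects for a catalog.

    A ``prop_null`` fraction of events get zero effect everywhere.  Each
    true target draws one direction (toward inclusion with probability
    ``prob_inclusion``) and responds in each cell line independently with
    probability ``response_rate`` (at least one line guaranteed), with
    magnitude |N(effect_mean_abs, effect_sd)| drawn per responsive line.
    ``discordant_rate`` of true targets respond with opposite signs in the
    two siRNAs.  Baseline ψ ~ Uniform(15, 85).
    """
    if not 0 <= prop_null <= 1 or not 0 <= discordant_rate <= 1:
        raise ValueError("prop_null and discordant_rate must be in [0, 1]")
    kd = DEFAULT_KD_TABLE if kd_table is None else kd_table
    _validate_kd_table(kd, cell_lines)
    rng = np.random.default_rng(seed)
    rows = []
    for ase in catalog:
        is_null = rng.random() < prop_null
        sign = 1.0 if rng.random() < prob_inclusion else -1.0
        discordant = (not is_null) and rng.random() < discordant_rate
        responsive = rng.random(len(cell_lines)) < response_rate
        if not is_null and not responsive.any():
            responsive[rng.integers(len(cell_lines))] = True
        for j, cl in enumerate(cell_lines):
            baseline = float(rng.uniform(15.0, 85.0))
            effect = 0.0
            if not is_null and responsive[j]:
                effect = sign * abs(rng.normal(effect_mean_abs, effect_sd))
            rows.append(
                {
                    "ase_id": ase.ase_id,
                    "cell_line": cl,
                    "baseline_psi": baseline,
                    "effect_dpsi": effect,
                    "discordant": discordant,
                }
            )
    effects = pd.DataFrame(rows)
    return TruthTable(effects=effects, kd=kd[kd["cell_line"].isin(cell_lines)].reset_index(drop=True))


def _validate_kd_table(kd: pd.DataFrame, cell_lines: Sequence[str]) -> None:
    required = {"cell_line", "sirna", "kd_fraction"}
    if not required.issubset(kd.columns):
        raise ValueError(f"kd_table must have columns {sorted(required)}")
    if ((kd["kd_fraction"] < 0) | (kd["kd_fraction"] > 1)).any():
        raise ValueError("kd_fraction must be in [0, 1]")
    for cl in cell_lines:
        sirnas = set(kd.loc[kd["cell_line"] == cl, "sirna"])
        if sirnas != set(SIRNAS):
            raise ValueError(f"kd_table must list exactly {SIRNAS} for cell line {cl!r}")


@dataclass(frozen=True)
class Sample:
    """One transfection well-plate: a cell line under one condition, one day."""

    cell_line: str
    condition: str
    batch_day: int


def generate_samples(
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES,
    batch_day: int = 1,
    split_sirna_days: bool = False,
) -> list[Sample]:
    """Sample sheet: one mock plus the two siRNA transfections per line.

    By default both siRNAs share the batch day (and hence the mock).  With
    ``split_sirna_days`` each siRNA runs on its own day with its own mock,
    so the two Δψ values carry independent control noise.
    """
    samples = []
    for cl in cell_lines:
        if split_sirna_days:
            for d, s in enumerate(SIRNAS):
                samples.append(Sample(cl, MOCK, batch_day + d))
                samples.append(Sample(cl, s, batch_day + d))
        else:
            samples.append(Sample(cl, MOCK, batch_day))
            for s in SIRNAS:
                samples.append(Sample(cl, s, batch_day))
    return samples


@dataclass(frozen=True)
class NoiseParams:
    """Technical-noise settings for trace / peak-table synthesis.

    ``amount_cv``: lognormal CV on each isoform's molar amount (the
    dominant driver of null Δψ noise; at the default 0.05 the null Δψ sd is
    ~2.5 points, leaving the 8-point calling threshold ~3 sd out).
    ``size_jitter_sd``: sd of the shared per-well multiplicative sizing
    error (sizing calibration drifts per run, so both amplicons of a well
    shift together).  ``baseline_sd``: additive Gaussian trace noise, in
    signal units; default gives peak SNR of roughly 50 for a mid-ψ event.
    """

    baseline_sd: float = 50.0
    size_jitter_sd: float = 0.02
    amount_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.size_jitter_sd < 0 or self.amount_cv < 0:
            raise ValueError("noise parameters must be >= 0")


ZERO_NOISE = NoiseParams(baseline_sd=0.0, size_jitter_sd=0.0, amount_cv=0.0)

#: Gaussian peak sd on the migration-time axis (instrument resolution)
PEAK_WIDTH_TIME = 0.02
#: total molar amount per event per well (arbitrary units)
TOTAL_MOLAR = 1.0


def _noisy_amounts(
    psi: float, rng: np.random.Generator, noise: NoiseParams
) -> tuple[float, float, float]:
    """(inclusion molar, exclusion molar, shared size factor) for one well."""
    inc = TOTAL_MOLAR * psi / 100.0
    exc = TOTAL_MOLAR * (1.0 - psi / 100.0)
    if noise.amount_cv > 0:
        inc *= float(np.exp(rng.normal(0.0, noise.amount_cv)))
        exc *= float(np.exp(rng.normal(0.0, noise.amount_cv)))
    size_factor = (
        float(np.exp(rng.normal(0.0, noise.size_jitter_sd))) if noise.size_jitter_sd > 0 else 1.0
    )
    return inc, exc, size_factor


def synthesize_trace(
    sample: Sample,
    catalog: Sequence[AseDefinition],
    truth: TruthTable,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    calibration: Optional[SizeCalibration] = None,
    time_step: float = 0.004,
    rng: Optional[np.random.Generator] = None,
) -> Trace:
    """Render one well's electropherogram for the given events.

    Each event contributes two Gaussian peaks of width
    :data:`PEAK_WIDTH_TIME` whose integrated areas equal molar amount ×
    amplicon length (mass-proportional fluorescence), centred at the
    ladder-map time of the jittered size.  In a physical screen each event
    occupies its own well, so screen-scale synthesis passes single-event
    catalogs here; multi-event catalogs are supported for compact demos.
    """
    cal = calibration or default_ladder()
    rng = np.random.default_rng(seed) if rng is None else rng
    t0 = float(cal.time_at(SIZE_MIN_BP - 15))
    t1 = float(cal.time_at(SIZE_MAX_BP + 25))
    time = np.arange(t0, t1, time_step)
    signal = np.zeros_like(time)
    norm = 1.0 / (PEAK_WIDTH_TIME * np.sqrt(2.0 * np.pi))
    for ase in catalog:
        psi = truth.true_psi(ase.ase_id, sample.cell_line, sample.condition)
        inc, exc, size_factor = _noisy_amounts(psi, rng, noise)
        for molar, size in (
            (inc, ase.size_inclusion_bp),
            (exc, ase.size_exclusion_bp),
        ):
            if molar <= 0:
                continue
            mass = molar * size  # fluorescence is mass-proportional
            centre = float(cal.time_at(size * size_factor))
            signal += mass * norm * np.exp(-0.5 * ((time - centre) / PEAK_WIDTH_TIME) ** 2)
    if noise.baseline_sd > 0:
        signal += rng.normal(0.0, noise.baseline_sd, size=time.size)
    return Trace(
        time=time,
        signal=signal,
        cell_line=sample.cell_line,
        condition=sample.condition,
        batch_day=sample.batch_day,
    )


def simulate_peak_table(
    catalog: Sequence[AseDefinition],
    truth: TruthTable,
    samples: Iterable[Sample],
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-quantified peak table bypassing trace synthesis and detection.

    One row per (sample, event, amplicon) with the called size and the
    area the instrument would have integrated (molar × size, with the same
    noise model as the trace path minus baseline noise).  Schema:
    cell_line, condition, batch_day, ase_id, amplicon, called_size_bp, area.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        for ase in catalog:
            psi = truth.true_psi(ase.ase_id, sample.cell_line, sample.condition)
            inc, exc, size_factor = _noisy_amounts(psi, rng, noise)
            for name, molar, size in (
                ("inclusion", inc, ase.size_inclusion_bp),
                ("exclusion", exc, ase.size_exclusion_bp),
            ):
                if molar <= 0:
                    continue
                # fluorescence mass reflects the true fragment; only the
                # called size carries the shared sizing error
                rows.append(
                    {
                        "cell_line": sample.cell_line,
                        "condition": sample.condition,
                        "batch_day": sample.batch_day,
                        "ase_id": ase.ase_id,
                        "amplicon": name,
                        "called_size_bp": size * size_factor,
                        "area": molar * size,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line",
            "condition",
            "batch_day",
            "ase_id",
            "amplicon",
            "called_size_bp",
            "area",
        ],
    )
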