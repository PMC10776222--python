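"""Synthetic vocal colonies with known cluster and overlap structure.

Every pipeline stage is testable without field recordings: archetype
unit types are rendered as harmonic frequency-modulated tones, each
individual draws its units from a configured repertoire distribution
over archetypes, and a *gradation* parameter morphs units part-way
toward another archetype to create intermediates. Units are laid out in
time so the song rule holds by construction (song bouts of ≥5 units of
≥2 types with sub-second gaps; call units isolated by >10 s), and white
noise is added at a configured SNR.

Archetypes are parametric tones rather than corvid-realistic calls on
purpose: the downstream stages only see spectrogram shape, so cluster
geometry — separation, gradation, per-individual repertoire
distributions (shared female pools vs private male pools) — is what the
generator controls, not realism.

All randomness flows from the single colony seed through named
``numpy`` substreams, so generation is reproducible unit by unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import VocalUnitRecord, write_audio, write_label_track

SAMPLE_RATE = 48_000


@dataclass
class ArchetypeSpec:
    """One archetypal unit type: a harmonic stack with sinusoidal FM."""

    archetype_id: str
    f0_hz: float
    n_harmonics: int = 3
    fm_depth_hz: float = 0.0
    fm_rate_hz: float = 5.0
    duration_s: float = 0.08
    amplitude_envelope: str = "attack-decay"  # or "flat"

    def __post_init__(self) -> None:
        if not 100.0 < self.f0_hz < 12_000.0:
            raise ValueError("f0_hz must lie in (100, 12000)")
        if not 0.05 <= self.duration_s <= 2.0:
            raise ValueError("duration_s must lie in [0.05, 2.0]")
        if self.amplitude_envelope not in ("flat", "attack-decay"):
            raise ValueError("amplitude_envelope must be 'flat' or 'attack-decay'")


@dataclass
class IndividualSpec:
    """One synthetic bird: repertoire distributions over archetype ids."""

    name: str
    sex: str  # F | M
    colony: str
    call_repertoire: dict[str, float]
    song_repertoire: dict[str, float] = field(default_factory=dict)
    vocal_rate: float = 120.0  # units per hour

    def __post_init__(self) -> None:
        for dist in (self.call_repertoire, self.song_repertoire):
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: repertoire distribution must sum to 1")


@dataclass
class ColonyConfig:
    archetypes: dict[str, ArchetypeSpec]
    individuals: list[IndividualSpec]
    n_units_total: int
    gradation_lambda: float = 0.0
    noise_snr_db: float = 30.0
    song_fraction: float = 0.0
    duration_jitter: float = 0.05
    f0_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.archetypes or not self.individuals:
            raise ValueError("need at least one archetype and one individual")
        if not 0.0 <= self.gradation_lambda <= 1.0:
            raise ValueError("gradation_lambda must lie in [0, 1]")
        for ind in self.individuals:
            for dist in (ind.call_repertoire, ind.song_repertoire):
                unknown = set(dist) - set(self.archetypes)
                if unknown:
                    raise ValueError(f"{ind.name}: unknown archetype(s) {sorted(unknown)}")


@dataclass
class Colony:
    """Generated colony: unit records, ground truth, per-unit waveforms."""

    records: list[VocalUnitRecord]
    ground_truth: pd.DataFrame
    unit_waves: dict[str, np.ndarray]
    config: ColonyConfig
    sample_rate: int = SAMPLE_RATE

    def write(self, out_dir: str | Path) -> Path:
        """Emit WAV + Audacity label TSV per recording + ground-truth CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_recording: dict[str, list[VocalUnitRecord]] = {}
        for r in self.records:
            by_recording.setdefault(r.recording_id, []).append(r)
        for rec_id, recs in by_recording.items():
            recs = sorted(recs, key=lambda r: r.start_s)
            n = int(math.ceil((recs[-1].end_s + 0.25) * self.sample_rate))
            timeline = np.zeros(n)
            for r in recs:
                start = int(round(r.start_s * self.sample_rate))
                wave = self.unit_waves[r.unit_id]
                timeline[start : start + wave.size] += wave
            write_audio(out_dir / f"{rec_id}.wav", timeline, self.sample_rate)
            write_label_track(recs, out_dir / f"{rec_id}.txt")
        self.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        return out_dir


def default_archetypes(n: int = 6) -> dict[str, ArchetypeSpec]:
    """Well-separated archetype bank: log-spaced fundamentals, varied FM."""
    f0s = np.geomspace(400.0, 5000.0, n)
    specs = {}
    for i, f0 in enumerate(f0s):
        aid = f"A{i}"
        specs[aid] = ArchetypeSpec(
            archetype_id=aid,
            f0_hz=float(f0),
            n_harmonics=2 + i % 3,
            fm_depth_hz=float(0.04 * f0 * (i % 2)),
            fm_rate_hz=20.0 + 10.0 * (i % 3),
            duration_s=0.06,
            amplitude_envelope="attack-decay" if i % 2 else "flat",
        )
    return specs


def _lerp(a: float, b: float, lam: float) -> float:
    return (1.0 - lam) * a + lam * b


def render_unit(
    spec: ArchetypeSpec,
    morph_to: ArchetypeSpec | None = None,
    lam: float = 0.0,
    noise_snr_db: float = math.inf,
    rng: np.random.Generator | None = None,
    duration_scale: float = 1.0,
    f0_scale: float = 1.0,
    sample_rate: int = SAMPLE_RATE,
) -> np.ndarray:
    """Render one unit: harmonic FM tone, optionally morphed.

    With ``morph_to`` given, every parameter is interpolated linearly by
    ``lam`` (0 → pure ``spec``, 1 → pure ``morph_to``). ``duration_scale``
    and ``f0_scale`` apply per-unit production jitter. White noise is
    added at ``noise_snr_db``; deterministic given the generator.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    tgt = morph_to if morph_to is not None else spec
    f0 = _lerp(spec.f0_hz, tgt.f0_hz, lam) * f0_scale
    n_harm = max(1, round(_lerp(spec.n_harmonics, tgt.n_harmonics, lam)))
    fm_depth = _lerp(spec.fm_depth_hz, tgt.fm_depth_hz, lam)
    fm_rate = _lerp(spec.fm_rate_hz, tgt.fm_rate_hz, lam)
    duration = _lerp(spec.duration_s, tgt.duration_s, lam) * duration_scale

    n = max(int(round(duration * sample_rate)), 16)
    t = np.arange(n) / sample_rate
    inst_freq = f0 + fm_depth * np.sin(2.0 * math.pi * fm_rate * t)
    phase = 2.0 * math.pi * np.cumsum(inst_freq) / sample_rate
    wave = np.zeros(n)
    nyquist = sample_rate / 2.0
    for k in range(1, n_harm + 1):
        if k * (f0 + abs(fm_depth)) < nyquist:
            wave += np.sin(k * phase) / k

    envelope_kind = spec.amplitude_envelope if lam < 0.5 else tgt.amplitude_envelope
    if envelope_kind == "attack-decay":
        attack = max(1, n // 5)
        env = np.ones(n)
        env[:attack] = np.linspace(0.0, 1.0, attack)
        env[attack:] = np.exp(-3.0 * (t[attack:] - t[attack]) / max(duration, 1e-6))
    else:
        env = np.ones(n)
        ramp = min(max(1, int(0.005 * sample_rate)), n // 2)
        env[:ramp] = np.linspace(0.0, 1.0, ramp)
        env[-ramp:] = np.linspace(1.0, 0.0, ramp)
    wave *= env

    if math.isfinite(noise_snr_db):
        rng = rng if rng is not None else np.random.default_rng(0)
        sig_power = np.mean(wave**2)
        noise_power = sig_power / (10.0 ** (noise_snr_db / 10.0))
        wave = wave + rng.normal(0.0, math.sqrt(noise_power), n)
    peak = np.max(np.abs(wave))
    return wave / peak * 0.9 if peak > 0 else wave


def _sample_types(rng: np.random.Generator, dist: dict[str, float], size: int) -> list[str]:
    ids = sorted(dist)
    probs = np.array([dist[a] for a in ids])
    return [ids[i] for i in rng.choice(len(ids), size=size, p=probs / probs.sum())]


def generate_colony(config: ColonyConfig) -> Colony:
    """Sample and render a full colony.

    Per individual, units split into song bouts (runs of 5–8 units with
    0.3–0.9 s gaps, forced to contain ≥2 archetype ids when the song
    repertoire allows) and isolated call units (gaps of 10.5–14 s, so
    the song rule never joins them). Each unit's archetype is drawn from
    the individual's repertoire; with ``gradation_lambda`` > 0 the unit
    is morphed toward a random other archetype by a per-unit mixing
    level drawn uniformly from [0, gradation_lambda]. Per-unit
    production jitter perturbs duration and pitch (``duration_jitter``,
    ``f0_jitter``) so clusters have realistic continuous within-type
    spread. Ground truth records archetype, morph target and level, and
    unit type.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.individuals))
    per_individual = max(1, config.n_units_total // len(config.individuals))
    arch_ids = sorted(config.archetypes)

    records: list[VocalUnitRecord] = []
    truth_rows = []
    unit_waves: dict[str, np.ndarray] = {}

    for ind, stream in zip(config.individuals, streams):
        rng = np.random.default_rng(stream)
        rec_id = f"rec_{ind.name}"
        n_song = int(round(config.song_fraction * per_individual)) if ind.song_repertoire else 0
        n_call = per_individual - n_song

        plan: list[tuple[str, str]] = [("call", a) for a in _sample_types(rng, ind.call_repertoire, n_call)]
        remaining = n_song
        while remaining > 0:
            bout_len = min(int(rng.integers(5, 9)), remaining)
            if bout_len < 5:
                bout_len = 5  # keep the run a valid song even on the tail
            bout = _sample_types(rng, ind.song_repertoire, bout_len)
            if len(set(bout)) < 2:
                alternatives = [a for a in ind.song_repertoire if a != bout[0]]
                if alternatives:
                    bout[int(rng.integers(0, bout_len))] = alternatives[
                        int(rng.integers(0, len(alternatives)))
                    ]
            plan.extend(("song", a) for a in bout)
            remaining -= bout_len

        t_cursor = 0.5
        prev_kind = None
        for i, (kind, arch_id) in enumerate(plan):
            spec = config.archetypes[arch_id]
            lam = 0.0
            morph_target = ""
            morph_spec = None
            if config.gradation_lambda > 0 and len(arch_ids) > 1:
                lam = float(rng.uniform(0.0, config.gradation_lambda))
                others = [a for a in arch_ids if a != arch_id]
                morph_target = others[int(rng.integers(0, len(others)))]
                morph_spec = config.archetypes[morph_target]
            scale = float(1.0 + rng.uniform(-config.duration_jitter, config.duration_jitter))
            f0_scale = float(1.0 + rng.uniform(-config.f0_jitter, config.f0_jitter))
            wave = render_unit(
                spec,
                morph_to=morph_spec,
                lam=lam,
                noise_snr_db=config.noise_snr_db,
                rng=rng,
                duration_scale=scale,
                f0_scale=f0_scale,
            )
            duration = wave.size / SAMPLE_RATE

            if prev_kind is None:
                gap = 0.0
            elif kind == "song" and prev_kind == "song":
                gap = float(rng.uniform(0.3, 0.9))
            else:
                gap = float(rng.uniform(10.5, 14.0))  # isolates calls and bout starts
            t_cursor += gap
            unit_id = f"{ind.name}_{i:05d}"
            records.append(
                VocalUnitRecord(
                    unit_id=unit_id,
                    recording_id=rec_id,
                    start_s=t_cursor,
                    end_s=t_cursor + duration,
                    individual=ind.name,
                    sex=ind.sex,
                    colony=ind.colony,
                    unit_type=kind,
                    type_tag=arch_id,
                )
            )
            truth_rows.append(
                {
                    "unit_id": unit_id,
                    "individual": ind.name,
                    "sex": ind.sex,
                    "colony": ind.colony,
                    "archetype_id": arch_id,
                    "morph_target": morph_target,
                    "morph_lambda": lam,
                    "unit_type": kind,
                }
            )
            unit_waves[unit_id] = wave
            t_cursor += duration
            prev_kind = kind

    # song bouts must not chain across the plan boundary within a bout:
    # bout starts always follow a >=10.5 s gap above, so runs are exact.
    return Colony(
        records=records,
        ground_truth=pd.DataFrame(truth_rows),
        unit_waves=unit_waves,
        config=config,
    )


def expected_overlap(
    config: ColonyConfig, unit_type: str = "call"
) -> tuple[np.ndarray, list[str]]:
    """Closed-form Morisita–Horn matrix on the *configured* repertoire
    distributions — the value a perfect pipeline recovers when
    archetypes are acoustically separable and ``gradation_lambda`` = 0.
    """
    arch_ids = sorted(config.archetypes)
    names = [ind.name for ind in config.individuals]
    vecs = []
    for ind in config.individuals:
        dist = ind.call_repertoire if unit_type == "call" else ind.song_repertoire
        vecs.append(np.array([dist.get(a, 0.0) for a in arch_ids]))
    m = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = vecs[i], vecs[j]
            m[i, j] = m[j, i] = 2.0 * np.sum(x * y) / (np.sum(x**2) + np.sum(y**2))
    return m, names


def empirical_overlap(colony: Colony, unit_type: str | None = "call") -> tuple[np.ndarray, list[str]]:
    """Morisita–Horn matrix on the *realized* per-individual archetype
    counts in the ground truth — the value a pipeline with perfect
    clustering recovers for this particular sample. Differs from
    :func:`expected_overlap` only by multinomial sampling noise, which
    shrinks as units per individual grow."""
    gt = colony.ground_truth
    if unit_type is not None:
        gt = gt[gt.unit_type == unit_type]
    arch_ids = sorted(colony.config.archetypes)
    names = [ind.name for ind in colony.config.individuals]
    vecs = []
    for name in names:
        counts = gt[gt.individual == name].archetype_id.value_counts()
        v = np.array([counts.get(a, 0) for a in arch_ids], dtype=float)
        vecs.append(v / v.sum() if v.sum() else v)
    m = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = vecs[i], vecs[j]
            denom = np.sum(x**2) + np.sum(y**2)
            m[i, j] = m[j, i] = 2.0 * np.sum(x * y) / denom if denom else np.nan
    return m, names


def balanced_colony(
    n_archetypes: int = 6,
    n_individuals: int = 4,
    units_per_individual: int = 150,
    noise_snr_db: float = 30.0,
    gradation_lambda: float = 0.0,
    song_fraction: float = 0.0,
    seed: int = 0,
) -> ColonyConfig:
    """All individuals share the uniform repertoire over all archetypes
    (the parameter-recovery study condition)."""
    archetypes = default_archetypes(n_archetypes)
    uniform = {a: 1.0 / n_archetypes for a in archetypes}
    individuals = [
        IndividualSpec(
            name=f"ind{i:02d}",
            sex="F" if i % 2 == 0 else "M",
            colony="S",
            call_repertoire=dict(uniform),
            song_repertoire=dict(uniform) if song_fraction > 0 else {},
        )
        for i in range(n_individuals)
    ]
    return ColonyConfig(
        archetypes=archetypes,
        individuals=individuals,
        n_units_total=units_per_individual * n_individuals,
        gradation_lambda=gradation_lambda,
        noise_snr_db=noise_snr_db,
        song_fraction=song_fraction,
        seed=seed,
    )


def varied_colony(
    n_archetypes: int = 6,
    n_individuals: int = 4,
    units_per_individual: int = 150,
    noise_snr_db: float = 30.0,
    gradation_lambda: float = 0.0,
    seed: int = 0,
) -> ColonyConfig:
    """Individuals with distinct but overlapping call repertoires.

    Individual ``i`` concentrates on three archetypes at indices
    ``(i + 2j) mod n`` with weights 0.4/0.3/0.3, so archetypes stay
    evenly sampled while expected pairwise Morisita–Horn overlaps span
    disjoint (0) to high — a sharper recovery target than identical
    repertoires.
    """
    archetypes = default_archetypes(n_archetypes)
    arch_ids = sorted(archetypes)
    individuals = []
    for i in range(n_individuals):
        window = [arch_ids[(i + 2 * j) % n_archetypes] for j in range(3)]
        individuals.append(
            IndividualSpec(
                name=f"ind{i:02d}",
                sex="F" if i % 2 == 0 else "M",
                colony="S",
                call_repertoire=dict(zip(window, (0.4, 0.3, 0.3))),
            )
        )
    return ColonyConfig(
        archetypes=archetypes,
        individuals=individuals,
        n_units_total=units_per_individual * n_individuals,
        gradation_lambda=gradation_lambda,
        noise_snr_db=noise_snr_db,
        seed=seed,
    )


def sex_structured_colony(
    n_females: int = 3,
    n_males: int = 3,
    shared_pool_size: int = 3,
    private_pool_size: int = 2,
    units_per_individual: int = 40,
    noise_snr_db: float = 30.0,
    seed: int = 0,
) -> ColonyConfig:
    """Females share one archetype pool; each male gets a private pool.

    Mimics the empirical sex contrast: homogeneous female call
    repertoires versus almost completely individual-specific male call
    repertoires, so female–female overlap exceeds male–male overlap.
    """
    n_arch = shared_pool_size + private_pool_size * n_males
    archetypes = default_archetypes(n_arch)
    arch_ids = sorted(archetypes)
    shared = arch_ids[:shared_pool_size]
    individuals = [
        IndividualSpec(
            name=f"F{i:02d}",
            sex="F",
            colony="S",
            call_repertoire={a: 1.0 / len(shared) for a in shared},
        )
        for i in range(n_females)
    ]
    for j in range(n_males):
        pool = arch_ids[shared_pool_size + j * private_pool_size :][:private_pool_size]
        individuals.append(
            IndividualSpec(
                name=f"M{j:02d}",
                sex="M",
                colony="S",
                call_repertoire={a: 1.0 / len(pool) for a in pool},
            )
        )
    return ColonyConfig(
        archetypes=archetypes,
        individuals=individuals,
        n_units_total=units_per_individual * (n_females + n_males),
        noise_snr_db=noise_snr_db,
        seed=seed,
    )
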