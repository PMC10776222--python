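"""End-to-end orchestration: corpus → spectrograms → DFTW matrix →
embedding → soft clusters → complexity indices → tidy exports.

The pipeline is deterministic given its seed; every tunable parameter
is serialized into a run manifest, and the distance matrix — the only
expensive stage — is cached on disk keyed by a checksum of its inputs,
so unchanged re-runs skip it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexity as cx
from . import corpus_io, dftw, embed_cluster, preprocessing

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    preprocess: preprocessing.PreprocessConfig = field(
        default_factory=preprocessing.PreprocessConfig
    )
    dftw: dftw.DftwConfig = field(default_factory=dftw.DftwConfig)
    n_neighbors: int = 30
    min_dist: float = 0.0
    min_samples: int = 30
    min_cluster_size: int = 30
    quality_k: int = 30
    seed: int = 20240110
    include_noise_profiles: bool = True
    flank_s: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


def extract_unit_segment(
    wave: np.ndarray,
    start_s: float,
    end_s: float,
    flank_s: float = 0.5,
    sample_rate: int = preprocessing.SAMPLE_RATE,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Cut a unit (channels × samples) plus its flanking context out of a
    recording timeline; flanks are used for SNR channel selection and
    noise profiling."""
    wave = np.atleast_2d(np.asarray(wave))
    i0, i1 = int(round(start_s * sample_rate)), int(round(end_s * sample_rate))
    i0, i1 = max(i0, 0), min(i1, wave.shape[1])
    if i1 <= i0:
        raise ValueError("empty unit segment")
    nf = int(round(flank_s * sample_rate))
    left = wave[:, max(i0 - nf, 0) : i0]
    right = wave[:, i1 : i1 + nf]
    flanks = np.concatenate([left, right], axis=1)
    return wave[:, i0:i1], (flanks if flanks.shape[1] > 0 else None)


def load_corpus_dir(corpus_dir: str | Path) -> tuple[list[corpus_io.VocalUnitRecord], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Load a directory of WAV recordings with Audacity label tracks.

    Each ``<recording>.wav`` must have a ``<recording>.txt`` label
    track; a ``ground_truth.csv`` (synthetic colonies) supplies sex and
    colony per individual when present. Returns (records, unit waves,
    unit flanks).
    """
    corpus_dir = Path(corpus_dir)
    meta: dict[str, tuple[str, str]] = {}
    gt_path = corpus_dir / "ground_truth.csv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path)
        for row in gt.itertuples(index=False):
            meta[str(row.individual)] = (str(row.sex), str(row.colony))

    records: list[corpus_io.VocalUnitRecord] = []
    unit_waves: dict[str, np.ndarray] = {}
    unit_flanks: dict[str, np.ndarray] = {}
    wavs = sorted(corpus_dir.glob("*.wav"))
    if not wavs:
        raise FileNotFoundError(f"no WAV recordings in {corpus_dir}")
    for wav_path in wavs:
        label_path = wav_path.with_suffix(".txt")
        if not label_path.exists():
            logger.warning("no label track for %s; skipped", wav_path.name)
            continue
        wave, sr = corpus_io.read_audio(wav_path)
        recs = corpus_io.read_label_track(label_path, recording_id=wav_path.stem)
        for r in recs:
            sex, colony = meta.get(r.individual, ("", ""))
            r.sex, r.colony = sex, colony
            r.channel_count = wave.shape[0]
            segment, flanks = extract_unit_segment(wave, r.start_s, r.end_s, sample_rate=sr)
            unit_waves[r.unit_id] = segment
            if flanks is not None:
                unit_flanks[r.unit_id] = flanks
            records.append(r)
    return records, unit_waves, unit_flanks


def _distance_checksum(spectrograms: list, config: dftw.DftwConfig) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(asdict(config), sort_keys=True).encode())
    for s in spectrograms:
        h.update(s.unit_id.encode())
        h.update(np.ascontiguousarray(s.values, dtype=np.float32).tobytes())
    return h.hexdigest()


def _cached_distances(cache_dir: Path, checksum: str, n: int) -> np.ndarray | None:
    meta_path, mat_path = cache_dir / "distances.meta.json", cache_dir / "distances.npy"
    if not (meta_path.exists() and mat_path.exists()):
        return None
    try:
        meta = json.loads(meta_path.read_text())
        if meta.get("checksum") != checksum:
            return None
        values = np.load(mat_path)
        if values.shape != (n, n):
            raise ValueError("shape mismatch")
        return values
    except Exception as exc:
        warnings.warn(f"corrupted distance cache ({exc}); recomputing", stacklevel=2)
        return None


def run_arrays(
    records: list[corpus_io.VocalUnitRecord],
    unit_waves: dict[str, np.ndarray],
    config: PipelineConfig | None = None,
    unit_flanks: dict[str, np.ndarray] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on in-memory units; optionally persist artifacts.

    Returns a results dict with the distance matrix, embedding, soft
    memberships, projection quality, per-unit gradation and
    per-individual diversity tables, repertoire profiles and overlap
    matrices/tables, plus the run manifest.
    """
    config = config or PipelineConfig()
    unit_flanks = unit_flanks or {}
    t_start = time.time()
    timings: dict[str, float] = {}

    records = corpus_io.filter_analysable(records)
    if any(r.unit_type == "unassigned" for r in records):
        records = corpus_io.classify_call_vs_song(records)
    if len(records) < 2:
        raise ValueError("pipeline needs at least two analysable units")

    t0 = time.time()
    spectrograms = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*zero-padding")
        for r in records:
            spectrograms.append(
                preprocessing.preprocess_unit(
                    unit_waves[r.unit_id],
                    unit_id=r.unit_id,
                    config=config.preprocess,
                    flanks=unit_flanks.get(r.unit_id),
                )
            )
    timings["preprocess_s"] = time.time() - t0

    t0 = time.time()
    checksum = _distance_checksum(spectrograms, config.dftw)
    cached = None
    cache_dir = Path(out_dir) if out_dir is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cached = _cached_distances(cache_dir, checksum, len(spectrograms))
    if cached is not None:
        dist = dftw.DistanceMatrix(values=cached, unit_ids=[r.unit_id for r in records])
        timings["dftw_cached"] = True
    else:
        dist = dftw.pairwise_distances(
            spectrograms, config.dftw, unit_ids=[r.unit_id for r in records]
        )
        if cache_dir is not None:
            np.save(cache_dir / "distances.npy", dist.values)
            (cache_dir / "distances.meta.json").write_text(
                json.dumps({"checksum": checksum, "n": len(dist)})
            )
    timings["dftw_s"] = time.time() - t0

    t0 = time.time()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_neighbors")
        emb = embed_cluster.embed(
            dist, n_neighbors=config.n_neighbors, min_dist=config.min_dist, seed=config.seed
        )
    n = len(records)
    k_quality = min(config.quality_k, (n - 1) // 2)
    quality = {
        "trustworthiness": embed_cluster.trustworthiness(dist, emb, k_quality),
        "continuity": embed_cluster.continuity(dist, emb, k_quality),
        "k": k_quality,
        "seed": config.seed,
        "params": emb.params,
    }
    timings["embed_s"] = time.time() - t0

    t0 = time.time()
    memberships, K = embed_cluster.cluster_soft(
        emb,
        min_samples=config.min_samples,
        min_cluster_size=config.min_cluster_size,
        dist=dist,
    )
    K_, frac_assigned, frac_noise = embed_cluster.assignment_summary(memberships)
    timings["cluster_s"] = time.time() - t0

    by_id = {m.unit_id: m for m in memberships}
    rec_by_id = {r.unit_id: r for r in records}

    gradation_rows = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="K=1")
        for r in records:
            for kind in ("shannon", "simpson"):
                gradation_rows.append(
                    {
                        "unit_id": r.unit_id,
                        "individual": r.individual,
                        "sex": r.sex,
                        "colony": r.colony,
                        "unit_type": r.unit_type,
                        "index_kind": kind,
                        "value": cx.unit_gradation(by_id[r.unit_id], kind).value,
                    }
                )
        gradation_df = pd.DataFrame(gradation_rows)

        profiles: list[cx.RepertoireProfile] = []
        groups: dict[tuple[str, str], list] = {}
        for r in records:
            groups.setdefault((r.individual, r.unit_type), []).append(by_id[r.unit_id])
            groups.setdefault((r.individual, "all"), []).append(by_id[r.unit_id])
        for (individual, unit_type), ms in sorted(groups.items()):
            rec = next(r for r in records if r.individual == individual)
            profiles.append(
                cx.build_profile(
                    ms,
                    individual,
                    unit_type,
                    sex=rec.sex,
                    colony=rec.colony,
                    include_noise=config.include_noise_profiles,
                )
            )

        diversity_rows = [
            {
                "individual": p.individual,
                "sex": p.sex,
                "colony": p.colony,
                "unit_type": p.unit_type,
                "n_units": p.n_units,
                "index_kind": kind,
                "value": cx.individual_diversity(p, kind).value,
            }
            for p in profiles
            for kind in ("shannon", "simpson")
        ]
        diversity_df = pd.DataFrame(diversity_rows)

    matrices = cx.overlap_matrices(profiles)
    overlap_df = cx.overlap_tidy_table(matrices, profiles)
    timings["total_s"] = time.time() - t_start

    manifest = {
        "config": config.to_dict(),
        "n_units": n,
        "seed": config.seed,
        "distance_checksum": checksum,
        "timings": timings,
    }

    results = {
        "records": records,
        "spectrograms": spectrograms,
        "distances": dist,
        "embedding": emb,
        "memberships": memberships,
        "K": K,
        "fraction_assigned": frac_assigned,
        "fraction_noise": frac_noise,
        "quality": quality,
        "gradation": gradation_df,
        "diversity": diversity_df,
        "profiles": profiles,
        "overlap_matrices": matrices,
        "overlap": overlap_df,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def _write_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus_io.write_unit_table(results["records"], out_dir / "unit_table.csv")
    emb = results["embedding"]
    pd.DataFrame(
        {"unit_id": emb.unit_ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
    ).to_csv(out_dir / "embedding.csv", index=False)
    mem = results["memberships"]
    K = results["K"]
    mem_df = pd.DataFrame(
        {
            "unit_id": [m.unit_id for m in mem],
            "hard_label": [m.hard_label for m in mem],
            **{f"p_{k}": [m.probs[k] for m in mem] for k in range(K)},
        }
    )
    mem_df.to_csv(out_dir / "memberships.csv", index=False)
    (out_dir / "quality.json").write_text(json.dumps(results["quality"], indent=2))
    cx.export_stats_tables(
        results["gradation"], results["diversity"], results["overlap"], out_dir
    )
    for name, mat in results["overlap_matrices"].items():
        pd.DataFrame(mat.values, index=mat.row_labels, columns=mat.col_labels).to_csv(
            out_dir / f"overlap_{name}.csv"
        )
    (out_dir / "manifest.json").write_text(json.dumps(results["manifest"], indent=2, default=str))


def run(
    corpus_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """File-based entry point: load a corpus directory, run all stages,
    write artifacts (unit table, embedding, memberships, quality report,
    index tables, overlap matrices, manifest) to ``out_dir``."""
    records, unit_waves, unit_flanks = load_corpus_dir(corpus_dir)
    return run_arrays(records, unit_waves, config, unit_flanks=unit_flanks, out_dir=out_dir)


def report(results: dict, recorded_hours: dict[str, float] | None = None) -> dict:
    """Machine-readable run summary: unit counts by sex/colony/type,
    cluster count, assignment fraction, projection quality, index
    medians by group, and per-individual vocalization rates when
    recording durations are supplied (units per hour)."""
    records = results["records"]
    counts: dict[str, dict[str, int]] = {"sex": {}, "colony": {}, "unit_type": {}}
    for r in records:
        counts["sex"][r.sex] = counts["sex"].get(r.sex, 0) + 1
        counts["colony"][r.colony] = counts["colony"].get(r.colony, 0) + 1
        counts["unit_type"][r.unit_type] = counts["unit_type"].get(r.unit_type, 0) + 1

    grad = results["gradation"]
    div = results["diversity"]
    grad_summary = (
        grad.groupby(["index_kind", "sex", "unit_type"])["value"].median().reset_index()
    )
    div_summary = (
        div.groupby(["index_kind", "sex", "unit_type"])["value"].median().reset_index()
    )

    summary = {
        "n_units": len(records),
        "counts": counts,
        "K": results["K"],
        "fraction_assigned": results["fraction_assigned"],
        "fraction_noise": results["fraction_noise"],
        "trustworthiness": results["quality"]["trustworthiness"],
        "continuity": results["quality"]["continuity"],
        "gradation_median": grad_summary.to_dict(orient="records"),
        "diversity_median": div_summary.to_dict(orient="records"),
    }
    if recorded_hours:
        by_ind: dict[str, int] = {}
        for r in records:
            by_ind[r.individual] = by_ind.get(r.individual, 0) + 1
        summary["vocalization_rate_per_h"] = {
            ind: n / recorded_hours[ind] for ind, n in by_ind.items() if ind in recorded_hours
        }
    # behavioural contexts are carried, not interpreted: tabulate frequencies
    contexts = [r.context for r in records if r.context]
    if contexts:
        tab: dict[str, int] = {}
        for c in contexts:
            tab[c] = tab.get(c, 0) + 1
        summary["context_counts"] = tab
    return summary
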