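"""End-to-end orchestration: simulate -> segment -> extract -> analyze.

``run_pipeline`` drives the whole synthetic study from one ``RunConfig`` and
writes a report bundle (JSON + human-readable text) with provenance (config
hash, seeds, library versions).  Every stochastic stage receives a child
seed derived from the master seed, so a config reproduces its numbers
bit-identically.  ``make_fixtures`` materializes the small standard datasets
used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decoding, extraction, invariance, population, spatial
from .core import Movie, TrialLayout
from .extraction import DetectionParams
from .segmentation import (SegmentationParams, match_regions_to_masks,
                           segment_movie)
from .synth import (SimConfig, concentration_series, generate_movie,
                    generate_response_dataset, generate_trial_traces,
                    odor_panel, write_ground_truth)

log = logging.getLogger("pirinv")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    movie_sim: SimConfig | None = None        # separate, smaller movie stage
    segmentation: SegmentationParams = field(
        default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    method: str = "lda-on-pcs"
    alpha: float = 0.01
    n_boot: int = 200
    nni_shuffles: int = 500
    seed: int = 0
    run_movie_stage: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        obj = json.loads(text)

        def sim_config(d: dict | None) -> SimConfig | None:
            if d is None:
                return None
            d = dict(d)
            d["trial_layout"] = TrialLayout(**d["trial_layout"])
            d["field_size"] = tuple(d["field_size"])
            d["stimulus_set"] = [(o, float(x)) for o, x in d["stimulus_set"]]
            return SimConfig(**d)

        return cls(
            sim=sim_config(obj["sim"]),
            movie_sim=sim_config(obj.get("movie_sim")),
            segmentation=SegmentationParams(**obj["segmentation"]),
            detection=DetectionParams(**obj["detection"]),
            method=obj["method"], alpha=obj["alpha"],
            n_boot=obj["n_boot"], nni_shuffles=obj["nni_shuffles"],
            seed=obj["seed"], run_movie_stage=obj["run_movie_stage"])

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_movie_sim(seed: int) -> SimConfig:
    """A small movie stage that segments in seconds: 64 x 64, 25 cells."""
    return SimConfig(field_size=(64, 64), n_cells=25, cell_radius=4.0,
                     stimulus_set=concentration_series(),
                     n_trials_per_stimulus=2, fraction_activated=0.8,
                     fraction_suppressed=0.0, fraction_invariant=0.4,
                     fraction_mixed=0.2, trial_noise_sd=0.0,
                     pixel_noise_sd=0.03, p_respond=0.9,
                     spontaneous_rate_hz=0.05, seed=seed)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "numpy_version": np.__version__,
        },
        "timings_s": {},
    }
    (out / "run_config.json").write_text(config.to_json())

    def stage(name: str):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        # -- 1. simulate the response dataset --------------------------------
        t0 = stage("simulate")
        sim = dataclasses.replace(config.sim, seed=seeds[0])
        table, gt = generate_response_dataset(sim)
        table.to_csv(out / "responses.csv")
        write_ground_truth(gt, out / "ground_truth.json")
        report["timings_s"]["simulate"] = time.perf_counter() - t0

        # -- 2. optional movie stage: segmentation on synthetic movie --------
        if config.run_movie_stage:
            t0 = stage("segment")
            movie_sim = config.movie_sim or default_movie_sim(seeds[1])
            movie, movie_gt = generate_movie(movie_sim)
            movie.to_tiff(out / "movie.tif")
            regions = segment_movie(movie, config.segmentation)
            ious = match_regions_to_masks(regions, movie_gt.cell_masks,
                                          movie.shape[1:])
            report["segmentation"] = {
                "n_planted": len(movie_gt.cell_masks),
                "n_regions": len(regions.pixels),
                "recovered_iou50_pct":
                    100.0 * float((ious >= 0.5).mean()),
                "mean_iou": float(ious.mean()),
            }
            report["timings_s"]["segment"] = time.perf_counter() - t0

        # -- 3. trial traces, detection, responsive fractions ----------------
        t0 = stage("detect")
        tensor, trace_gt = generate_trial_traces(sim)
        rate = extraction.deconvolve(tensor.data, sim.kernel_tau,
                                     sim.frame_rate)
        rate_tensor = dataclasses.replace(tensor, data=rate)
        flags = extraction.detect_responses_tensor(tensor, config.detection)
        fractions = population.responsive_fractions(flags)
        report["responsive_fractions"] = {
            "activated_pct_mean": float(fractions["activated_pct"].mean()),
            "suppressed_pct_mean": float(fractions["suppressed_pct"].mean()),
        }
        report["timings_s"]["detect"] = time.perf_counter() - t0

        # -- 4. population vectors, correlations, sparseness ------------------
        t0 = stage("population")
        vec_table = population.build_population_vectors(rate_tensor)
        corr, meta = population.correlation_matrix(vec_table)
        report["correlation_summary"] = population.summarize_correlations(
            corr, meta)
        sl = population.sparseness_per_cell(table)
        report["lifetime_sparseness"] = {
            "mean": float(sl.mean()), "sd": float(sl.std()),
        }
        report["timings_s"]["population"] = time.perf_counter() - t0

        # -- 5. decoding ------------------------------------------------------
        t0 = stage("decode")
        mat, mmeta = table.matrix()
        labels = (mmeta["odorant"].astype(str) + "@"
                  + mmeta["dilution"].astype(str)).to_numpy()
        loo = decoding.classify_loo(mat.T, labels, config.method)
        report["decoding"] = {"identity_accuracy_pct": loo.accuracy,
                              "identity_chance_pct": loo.chance}
        if len({d for _, d in table.stimuli}) == 3:
            gen = decoding.concentration_generalization(table, config.method)
            report["decoding"]["generalization_accuracy_pct"] = gen.accuracy
            report["decoding"]["generalization_100fold_pct"] = \
                gen.extras["accuracy_100fold"]
        report["timings_s"]["decode"] = time.perf_counter() - t0

        # -- 6. invariance statistics -----------------------------------------
        t0 = stage("invariance")
        inv = invariance.classify_population(table, config.alpha)
        inv["cells"].to_csv(out / "anova_cells.csv", index=False)
        boot = invariance.bootstrap_identity_shuffle(
            table, n_boot=config.n_boot, seed=seeds[2], alpha=config.alpha)
        report["invariance"] = {
            "invariant_pct": inv["invariant_pct"],
            "invariant_pct_of_identity_sig":
                inv["invariant_pct_of_identity_sig"],
            "fractions_pct": inv["fractions_pct"],
            "bootstrap_null_mean_pct": float(boot.null_fractions.mean()),
            "bootstrap_p": boot.p,
        }
        report["timings_s"]["invariance"] = time.perf_counter() - t0

        # -- 7. spatial organization ------------------------------------------
        t0 = stage("spatial")
        rng = np.random.default_rng(seeds[3])
        positions = rng.uniform(0, 300, size=(table.n_cells, 2))
        labels = inv["cells"]["category"].to_numpy()
        cmap = spatial.CellMap(positions=positions, labels=labels)
        cmap.to_csv(out / "cell_map.csv")
        nni = spatial.nni_shuffle_test(cmap, n_shuffles=config.nni_shuffles,
                                       seed=seeds[4])
        report["spatial"] = {
            "pooled_nni_um": nni["pooled_nni"],
            "pooled_p": nni["pooled_p"],
            "per_class_p": {str(k): v for k, v in nni["p"].items()},
        }
        report["timings_s"]["spatial"] = time.perf_counter() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline failed in a stage: {err}") from err

    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = ["pipeline report", "===============", ""]

    def walk(obj, indent=0):
        for k, v in obj.items():
            if isinstance(v, dict):
                lines.append("  " * indent + f"{k}:")
                walk(v, indent + 1)
            else:
                if isinstance(v, float):
                    v = f"{v:.4g}"
                lines.append("  " * indent + f"{k}: {v}")

    walk(report)
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def toy_movie_signals() -> np.ndarray:
    """The schematic 3 x 3 pixels x 6 frames clustering example.

    Two planted 2-pixel sources — pixels (0,0),(0,1) and (2,1),(2,2) share
    perfectly correlated signals — on a background of small uncorrelated
    values, so the first two greedy merges must join the planted pairs.
    Returns the movie as (6, 3, 3).
    """
    rng = np.random.default_rng(123)
    movie = 0.01 * rng.normal(size=(6, 3, 3))
    s1 = np.array([1.0, 0.0, 2.0, 0.0, 3.0, 0.0])
    s2 = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 3.0])
    movie[:, 0, 0] = s1
    movie[:, 0, 1] = 2.0 * s1 + 0.5        # affine copy: correlation 1
    movie[:, 2, 1] = s2
    movie[:, 2, 2] = 0.5 * s2 + 1.0
    return movie


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the small standard datasets used by the tests and demos."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy = Movie(data=toy_movie_signals(), frame_rate=1.0)
    paths["toy_movie"] = out / "toy_movie_3x3.tif"
    toy.to_tiff(paths["toy_movie"])

    demo_sim = default_movie_sim(seed)
    movie, gt = generate_movie(demo_sim)
    paths["demo_movie"] = out / "demo_movie_64x64.tif"
    movie.to_tiff(paths["demo_movie"])
    paths["demo_ground_truth"] = out / "demo_ground_truth.json"
    write_ground_truth(gt, paths["demo_ground_truth"],
                       field_size=demo_sim.field_size)

    table_sim = SimConfig(n_cells=300, seed=seed + 1)
    table, tgt = generate_response_dataset(table_sim)
    paths["response_table"] = out / "responses_300cells.csv"
    table.to_csv(paths["response_table"])
    paths["response_ground_truth"] = out / "responses_300cells_truth.json"
    write_ground_truth(tgt, paths["response_ground_truth"])

    null_sim = SimConfig(n_cells=300, fraction_activated=0.0,
                         fraction_suppressed=0.0, fraction_invariant=0.0,
                         fraction_mixed=0.0, seed=seed + 2)
    null_table, _ = generate_response_dataset(null_sim)
    paths["null_table"] = out / "null_site_300cells.csv"
    null_table.to_csv(paths["null_table"])
    return paths
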