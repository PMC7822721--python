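"""End-to-end analysis pipeline.

Chains the full procedure — preprocessing, circadian rhythm modeling,
and morningness-eveningness clustering — into one reproducible run that
writes flat CSV artifacts plus a JSON manifest.  All randomness (EM
restarts, k-means seeding) derives from a single run seed, so identical
config + seed reproduces byte-identical outputs.

Artifacts written to the output directory:

- ``preprocess_summary.csv``   cohort counts and per-person quartiles
- ``empirical_profiles.csv``   persons x 24 empirical hourly frequencies
- ``model_profiles.csv``       persons x 24 modeled bin masses
- ``squared_errors.csv``       persons x 24 squared differences
- ``fits.csv``                 mixture parameters + KS goodness of fit
- ``ranked_modes.csv``         activity periods in dominance order
- ``clusters.csv`` / ``centroids.csv``  chronotype clustering
- ``manifest.json``            config, seeds, package versions
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cdr_io import (
    CallRecordSet,
    PreprocessSummary,
    filter_active_participants,
    filter_outgoing,
    read_cdr,
    select_common_window,
    write_cdr,
)
from .chronotype import ModeRanking, extract_modes, rank_modes
from .clustering import ClusterResult, embed, kmeans, label_clusters
from .rhythm_model import (
    GoodnessOfFit,
    MixtureFit,
    discretize,
    empirical_frequency,
    ks_goodness_of_fit,
    model_profile,
    observed_call_hours,
)
from .synthetic_data import PopulationConfig, generate_population, load_scenario

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` feeds every random stage."""

    #: CDR CSV to analyze; when absent, a cohort is simulated from
    #: ``scenario_path`` (or the default scenario if that is absent too)
    input_path: str | Path | None = None
    scenario_path: str | Path | None = None
    outdir: str | Path = "chronocall_out"
    window_months: int = 12
    K: int = 2
    wrapped: bool = True
    alpha: float = 0.05
    k_clusters: int = 2
    metric: str = "euclidean"
    n_init_em: int = 10
    n_init_kmeans: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PipelineError("config: a seed is required (no silent nondeterminism)")


def simulate(
    scenario_path: str | Path | None,
    seed: int,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Generate a synthetic CDR file plus its ground-truth sidecar.

    With no scenario file the default cohort (26 persons, 12 months)
    is produced.  Returns (cdr_path, truth_path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario_path is None:
        config = PopulationConfig(seed=seed)
    else:
        config = load_scenario(scenario_path, seed=seed)
    records, truth = generate_population(config)
    cdr_path = outdir / "cdr.csv"
    write_cdr(records, cdr_path)
    truth_path = outdir / "ground_truth.csv"
    truth.to_frame().to_csv(truth_path, index=False)
    logger.info("simulated %d records for %d persons -> %s",
                len(records), len(truth.profiles), cdr_path)
    return cdr_path, truth_path


# -- pipeline stages --------------------------------------------------------

def preprocess_stage(
    records: CallRecordSet, window_months: int
) -> tuple[CallRecordSet, PreprocessSummary]:
    """Outgoing filter, common-window selection, full-period activity filter."""
    outgoing = filter_outgoing(records)
    window = select_common_window(outgoing, window_months)
    kept, summary = filter_active_participants(outgoing, window)
    if summary.n_after == 0:
        raise PipelineError("preprocess: zero retained participants")
    return kept, summary


def fit_stage(
    records: CallRecordSet,
    K: int,
    wrapped: bool,
    alpha: float,
    n_init: int,
    seed_seq: np.random.SeedSequence,
) -> tuple[dict[str, MixtureFit], dict[str, GoodnessOfFit], pd.DataFrame]:
    """Per person: empirical profile, mixture fit, KS goodness of fit.

    Returns the fits, the goodness-of-fit results, and the empirical
    frequency matrix (persons x 24).
    """
    from .rhythm_model import fit_gmm  # local import keeps module load light

    persons = records.persons
    fits: dict[str, MixtureFit] = {}
    gofs: dict[str, GoodnessOfFit] = {}
    emp_rows = {}
    children = seed_seq.spawn(len(persons))
    for pid, child in zip(persons, children):
        hours = observed_call_hours(records, pid)
        emp_rows[pid] = empirical_frequency(discretize(records, pid)).freqs
        fit = fit_gmm(hours, K=K, wrapped=wrapped, n_init=n_init,
                      seed=np.random.default_rng(child))
        fits[pid] = fit
        gofs[pid] = ks_goodness_of_fit(hours, fit, alpha=alpha)
    emp = pd.DataFrame.from_dict(emp_rows, orient="index",
                                 columns=[f"h{t:02d}" for t in range(24)])
    emp.index.name = "person_id"
    return fits, gofs, emp


def cluster_stage(
    fits: dict[str, MixtureFit],
    k: int,
    metric: str,
    n_init: int,
    seed_seq: np.random.SeedSequence,
) -> tuple[list[ModeRanking], ClusterResult]:
    """Mode extraction, dominance ranking, embedding, k-means, labels."""
    rankings = [rank_modes(extract_modes(fit), person_id=pid) for pid, fit in fits.items()]
    points = embed(rankings)
    if len(points) == 0:
        raise PipelineError("cluster: no embeddable persons (all single-period fits)")
    result = kmeans(points, k=k, n_init=n_init, metric=metric,
                    seed=np.random.default_rng(seed_seq.spawn(1)[0]))
    if k == 2:
        result = label_clusters(result)
    return rankings, result


# -- artifact writers -------------------------------------------------------

def _hour_frame(rows: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"h{t:02d}" for t in range(24)])
    df.index.name = "person_id"
    return df


def fits_table(fits: dict[str, MixtureFit], gofs: dict[str, GoodnessOfFit]) -> pd.DataFrame:
    rows = []
    for pid, fit in fits.items():
        row: dict = {"person_id": pid, "K": fit.K}
        for k in range(fit.K):
            row[f"mu{k + 1}"] = fit.means[k]
            row[f"sigma{k + 1}"] = float(np.sqrt(fit.variances[k]))
            row[f"pi{k + 1}"] = fit.weights[k]
        row["loglik"] = fit.loglik
        row["converged"] = fit.converged
        g = gofs[pid]
        row["ks_D"] = g.ks_statistic
        row["ks_p"] = g.p_value
        row["ks_reject"] = g.reject
        rows.append(row)
    return pd.DataFrame(rows)


def modes_table(rankings: list[ModeRanking]) -> pd.DataFrame:
    rows = []
    for r in rankings:
        row = {
            "person_id": r.person_id,
            "primary_peak": r.primary.peak_hour,
            "primary_sigma": r.primary.spread,
            "primary_weight": r.primary.weight,
        }
        if len(r.periods) > 1:
            row.update(
                secondary_peak=r.secondary.peak_hour,
                secondary_sigma=r.secondary.spread,
                secondary_weight=r.secondary.weight,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all artifacts.

    Returns the output directory.  Any stage failure raises
    :class:`PipelineError` tagged with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    root = np.random.SeedSequence(config.seed)
    sim_seq, fit_seq, cluster_seq = root.spawn(3)

    if config.input_path is not None:
        records = read_cdr(config.input_path)
    else:
        sim_seed = int(sim_seq.generate_state(1)[0] % (2**31))
        cdr_path, _ = simulate(config.scenario_path, sim_seed, outdir)
        records = read_cdr(cdr_path)
    logger.info("loaded %d records, %d persons", len(records), len(records.persons))

    kept, summary = preprocess_stage(records, config.window_months)
    summary.to_frame().to_csv(outdir / "preprocess_summary.csv", index=False)
    logger.info("preprocess: %d -> %d persons, %d calls [%.2fs]",
                summary.n_before, summary.n_after, summary.total_calls,
                time.perf_counter() - t0)

    fits, gofs, emp = fit_stage(
        kept, config.K, config.wrapped, config.alpha, config.n_init_em, fit_seq
    )
    emp.to_csv(outdir / "empirical_profiles.csv")
    _hour_frame({p: model_profile(f) for p, f in fits.items()}).to_csv(
        outdir / "model_profiles.csv"
    )
    _hour_frame({p: gofs[p].squared_errors for p in fits}).to_csv(
        outdir / "squared_errors.csv"
    )
    fits_table(fits, gofs).to_csv(outdir / "fits.csv", index=False)
    logger.info("fit: %d persons modeled [%.2fs]", len(fits), time.perf_counter() - t0)

    rankings, result = cluster_stage(
        fits, config.k_clusters, config.metric, config.n_init_kmeans, cluster_seq
    )
    modes_table(rankings).to_csv(outdir / "ranked_modes.csv", index=False)
    points = {p.person_id: p for p in embed(rankings)}
    cluster_rows = pd.DataFrame(
        [
            {
                "person_id": pid,
                "x": points[pid].x,
                "y": points[pid].y,
                "cluster": c,
                "label": result.labels.get(c, ""),
            }
            for pid, c in result.assignments.items()
        ]
    )
    cluster_rows.to_csv(outdir / "clusters.csv", index=False)
    pd.DataFrame(
        {
            "cluster": range(result.k),
            "x": result.centroids[:, 0],
            "y": result.centroids[:, 1],
            "label": [result.labels.get(c, "") for c in range(result.k)],
        }
    ).to_csv(outdir / "centroids.csv", index=False)

    manifest = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "versions": {
            "chronocall": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_persons_before": summary.n_before,
        "n_persons_after": summary.n_after,
        "kmeans_inertia": result.inertia,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete [%.2fs] -> %s", time.perf_counter() - t0, outdir)
    return outdir
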