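"""Synthetic barcode worlds with planted environment-diversity structure.

Generates every input the analysis pipeline consumes — a BOLD-schema
specimen table, pre-aligned per-OTU sequence sets simulated under the
coalescent, a per-cell environmental table — together with a truth record
holding the planted quantities (per-OTU theta, slopes, pathology counts)
so that every pipeline stage can be checked against construction.

The world emulates the *shape* of real barcode + climate-raster data, not
its content: environments are Gaussian random fields with exponential
covariance (a stand-in for the smooth spatial structure of climate
layers), and the cell-level diversity target is a linear function of
standardized predictors plus a spatial field plus noise.  Per-OTU
mutation-rate parameters are scattered log-normally around the cell
target, and sequences are simulated with the single-population coalescent
of :mod:`macrogd.coalescent`, so per-cell summaries recomputed from the
emitted alignments match the pipeline's output exactly.

Everything is reproducible end to end from one master seed; sub-streams
are spawned deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import bold_io
from .coalescent import CoalescentParams, simulate_coalescent_alignment
from .gridding import GridSpec, cell_bounds, cell_label, unproject

#: taxonomic orders and sampling weights mirroring barcode-survey prevalence
ORDER_WEIGHTS = {
    "Diptera": 0.340,
    "Lepidoptera": 0.324,
    "Hymenoptera": 0.173,
    "Coleoptera": 0.090,
    "Hemiptera": 0.045,
    "Trichoptera": 0.028,
}

#: raw-unit (mean, sd) used to de-standardize the simulated fields so the
#: environment table looks like physical units; mtcm straddles 0 C so both
#: freeze classes occur
ENV_UNITS = {
    "mtwm": (28.0, 5.0),
    "mtcm": (2.0, 8.0),
    "pwm": (180.0, 60.0),
    "pdm": (30.0, 20.0),
    "temp_seasonality": (600.0, 150.0),
    "precip_seasonality": (50.0, 20.0),
    "habitat_heterogeneity": (0.4, 0.15),
    "human_modification": (0.3, 0.15),
    "temp_trend": (0.02, 0.01),
    "temp_variation": (0.05, 0.02),
    "precip_trend": (0.1, 0.05),
    "precip_variation": (0.2, 0.08),
}


@dataclass(frozen=True)
class SyntheticWorld:
    """Configuration of a synthetic barcode world.

    The grid block spans ``n_rows x n_cols`` cells starting at
    (``row0``, ``col0``); with the default 193 km grid and ``row0 = 10``
    the block sits in the subtropics (~30-45 N).  ``true_slopes`` act on
    standardized predictors and are expressed on the sqrt-GDM scale of the
    cell target; ``gp_range`` and ``gp_sd`` control the spatial
    autocorrelation of the environment fields and of the response's
    residual field; per-OTU theta scatters log-normally (sd
    ``theta_log_sd`` on the log scale, mean-one multiplier) around the
    cell target.
    """

    grid: GridSpec = dc_field(default_factory=GridSpec)
    n_rows: int = 6
    n_cols: int = 6
    row0: int = 10
    col0: int = 0
    otus_per_cell: int = 30
    samples_per_otu: int = 5
    seq_length: int = 600
    mu: float = 1e-8
    intercept: float = 0.15
    true_slopes: dict = dc_field(
        default_factory=lambda: {"mtwm": 0.03, "precip_seasonality": -0.02, "temp_trend": 0.02}
    )
    gp_range: float = 600_000.0  # meters
    gp_sd: float = 0.01  # response spatial field sd (sqrt-GDM scale)
    noise_sd: float = 0.01  # iid cell noise (sqrt-GDM scale)
    theta_log_sd: float = 0.6
    n_multicell_otus: int = 2
    multicell_span: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("world must contain at least one cell")
        unknown = set(self.true_slopes) - set(ENV_UNITS)
        if unknown:
            raise ValueError(f"slopes on unknown predictors: {sorted(unknown)}")


@dataclass
class WorldData:
    """A generated world: records, alignments, environment, truth."""

    records: pd.DataFrame
    alignments: dict
    env: pd.DataFrame
    truth: dict
    invasive_list: set = dc_field(default_factory=set)


def _gp_field(coords: np.ndarray, range_m: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field with exponential covariance."""
    k = np.exp(-cdist(coords, coords) / range_m)
    k[np.diag_indices_from(k)] += 1e-10
    return np.linalg.cholesky(k) @ rng.standard_normal(coords.shape[0])


def _continent_of_col(col: int, col0: int, n_cols: int) -> str:
    """Split the block into two longitudinal 'continents' for stratification
    and invasive-taxon logic."""
    return "WestContinent" if (col - col0) < max(n_cols // 2, 1) else "EastContinent"


def generate_world(spec: SyntheticWorld) -> WorldData:
    """Generate a synthetic world per ``spec``.

    Returns records (BOLD schema), alignments keyed by (cell, otu),
    the per-cell environment table (raw units, indexed by cell), and the
    truth record with planted thetas, slopes and targets.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_env, rng_theta, rng_seq, rng_geo, rng_tax = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    cells = [
        (spec.row0 + i, spec.col0 + j)
        for i in range(spec.n_rows)
        for j in range(spec.n_cols)
    ]
    labels = [cell_label(r, c) for r, c in cells]
    centroids = np.array(
        [
            [(b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0]
            for b in (cell_bounds(r, c, spec.grid) for r, c in cells)
        ]
    )

    # spatially autocorrelated standardized environment fields
    env_z = pd.DataFrame(
        {name: _gp_field(centroids, spec.gp_range, rng_env) for name in ENV_UNITS},
        index=labels,
    )
    env_raw = pd.DataFrame(
        {name: ENV_UNITS[name][0] + ENV_UNITS[name][1] * env_z[name] for name in ENV_UNITS},
        index=labels,
    )
    env_raw.index.name = "cell"

    # planted cell target on the sqrt-GDM scale: linear predictor + field + noise
    lin = np.full(len(labels), spec.intercept)
    for name, slope in spec.true_slopes.items():
        lin = lin + slope * env_z[name].to_numpy()
    w_field = spec.gp_sd * _gp_field(centroids, spec.gp_range, rng_env)
    noise = spec.noise_sd * rng_env.standard_normal(len(labels))
    target = lin + w_field + noise
    n_clipped = int((target < 0.02).sum())
    target = np.maximum(target, 0.02)

    records = []
    rec_cells: list[str] = []
    alignments: dict[tuple[str, str], list[str]] = {}
    thetas: dict[str, dict[str, float]] = {}
    otu_counter = 0
    rec_counter = 0

    def emit_otu(otu_id: str, species: str, order: str, cell_idx: int, theta: float) -> None:
        nonlocal rec_counter
        label = labels[cell_idx]
        r, c = cells[cell_idx]
        seqs = simulate_coalescent_alignment(
            CoalescentParams(
                n_samples=spec.samples_per_otu,
                Ne=max(theta / (2.0 * spec.mu), 1e-6),
                mu=spec.mu,
                seq_length=spec.seq_length,
            ),
            rng_seq,
        )
        alignments[(label, otu_id)] = seqs
        x0, y0, x1, y1 = cell_bounds(r, c, spec.grid)
        eps = spec.grid.cell_size * 1e-6
        xs = rng_geo.uniform(x0 + eps, x1 - eps, size=len(seqs))
        ys = rng_geo.uniform(y0 + eps, y1 - eps, size=len(seqs))
        lat, lon = unproject(xs, ys, spec.grid)
        continent = _continent_of_col(c, spec.col0, spec.n_cols)
        for k, seq in enumerate(seqs):
            rec_counter += 1
            rec_cells.append(label)
            records.append(
                {
                    "processid": f"SYN{rec_counter:07d}",
                    "bin_uri": otu_id,
                    "order_name": order,
                    "species_name": species,
                    "lat": round(float(lat[k]), 6),
                    "lon": round(float(lon[k]), 6),
                    "country": continent,
                    "continent": continent,
                    "nucleotides": seq,
                }
            )
        thetas.setdefault(label, {})[otu_id] = theta

    order_names = list(ORDER_WEIGHTS)
    order_p = np.array(list(ORDER_WEIGHTS.values()))
    order_p = order_p / order_p.sum()

    for ci, label in enumerate(labels):
        mean_pi = target[ci] ** 2
        for _ in range(spec.otus_per_cell):
            otu_counter += 1
            otu_id = f"BOLD:SYN{otu_counter:05d}"
            mult = rng_theta.lognormal(-0.5 * spec.theta_log_sd**2, spec.theta_log_sd)
            order = order_names[rng_tax.choice(len(order_names), p=order_p)]
            emit_otu(otu_id, f"Synthetica cellularis{otu_counter}", order, ci, mean_pi * mult)

    # planted multi-cell OTUs (for occupancy checks); sampled in `span` cells
    multicell = {}
    for _ in range(spec.n_multicell_otus):
        otu_counter += 1
        otu_id = f"BOLD:SYN{otu_counter:05d}"
        span = min(spec.multicell_span, len(labels))
        chosen = rng_geo.choice(len(labels), size=span, replace=False)
        order = order_names[rng_tax.choice(len(order_names), p=order_p)]
        for ci in chosen:
            mean_pi = target[ci] ** 2
            mult = rng_theta.lognormal(-0.5 * spec.theta_log_sd**2, spec.theta_log_sd)
            emit_otu(otu_id, f"Synthetica vagans{otu_counter}", order, int(ci), mean_pi * mult)
        multicell[otu_id] = int(span)

    records_df = pd.DataFrame(records)
    truth = {
        "seed": spec.seed,
        "cell_size": spec.grid.cell_size,
        "cells": labels,
        "cell_of_record": dict(zip(records_df["processid"], rec_cells)),
        "target_sqrt_gdm": dict(zip(labels, map(float, target))),
        "n_target_clipped": n_clipped,
        "true_slopes": dict(spec.true_slopes),
        "intercept": spec.intercept,
        "theta": thetas,
        "multicell_otus": multicell,
        "n_records": len(records_df),
        "otus_per_cell": spec.otus_per_cell,
        "samples_per_otu": spec.samples_per_otu,
        "pathologies": {},
    }
    return WorldData(records=records_df, alignments=alignments, env=env_raw, truth=truth)


def inject_pathologies(
    world: WorldData,
    n_too_long: int = 3,
    n_too_short: int = 3,
    n_ungeoreferenced: int = 3,
    n_end_gap: int = 3,
    seed: int = 1,
) -> WorldData:
    """Append records violating each record-level filter, with labeled counts.

    Adds: over-length (>800 bp) and under-length (<400 bp) sequences,
    records with missing coordinates, sequences padded with end gaps (which
    must survive filtering after trimming), one listed invasive OTU present
    on two continents (all its records must be removed), and one OTU with
    only two copies in a cell (passes record filters but is excluded from
    the diversity computation).  The truth record gains exact expected
    removal counts per rule.
    """
    rng = np.random.default_rng(seed)
    records = world.records.copy()
    labels = world.truth["cells"]
    grid = GridSpec(cell_size=world.truth["cell_size"])

    def point_in(label: str) -> tuple[float, float]:
        from .gridding import parse_cell_label

        r, c = parse_cell_label(label)
        x0, y0, x1, y1 = cell_bounds(r, c, grid)
        eps = grid.cell_size * 1e-6
        x = rng.uniform(x0 + eps, x1 - eps)
        y = rng.uniform(y0 + eps, y1 - eps)
        lat, lon = unproject(x, y, grid)
        return round(float(lat), 6), round(float(lon), 6)

    def random_seq(length: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))

    new_rows = []
    counter = [len(records)]

    def add(otu, order, species, label, seq, lat=None, lon=None, continent=None):
        counter[0] += 1
        if lat is None and label is not None:
            lat, lon = point_in(label)
        new_rows.append(
            {
                "processid": f"PATH{counter[0]:07d}",
                "bin_uri": otu,
                "order_name": order,
                "species_name": species,
                "lat": lat,
                "lon": lon,
                "country": continent or "WestContinent",
                "continent": continent or "WestContinent",
                "nucleotides": seq,
            }
        )

    home = labels[0]
    for i in range(n_too_long):
        add(f"BOLD:PTLONG{i}", "Diptera", f"Pathologica longa{i}", home, random_seq(850))
    for i in range(n_too_short):
        add(f"BOLD:PTSHRT{i}", "Diptera", f"Pathologica brevis{i}", home, random_seq(300))
    for i in range(n_ungeoreferenced):
        add(
            f"BOLD:PTNOGEO{i}",
            "Diptera",
            f"Pathologica vaga{i}",
            None,
            random_seq(600),
            lat=np.nan,
            lon=np.nan,
        )
    # end-gap records: one new OTU with n_end_gap copies; retained after trimming
    endgap_otu = "BOLD:PTENDGAP"
    base = random_seq(600)
    for i in range(n_end_gap):
        seq = "-" * 10 + (base if i == 0 else random_seq(600)) + "-" * 10
        add(endgap_otu, "Hemiptera", "Pathologica marginata", home, seq)
    # invasive OTU on two continents, 3 copies each
    invasive_species = "Invasia invasiva"
    west = labels[0]
    east = labels[-1]
    inv_seqs = [random_seq(600) for _ in range(3)]
    for label, continent in ((west, "WestContinent"), (east, "EastContinent")):
        for i in range(3):
            add("BOLD:PTINVAS", "Coleoptera", invasive_species, label, inv_seqs[i], continent=continent)
    # low-copy OTU: 2 copies in one cell
    for i in range(2):
        add("BOLD:PTLOWCP", "Trichoptera", "Pathologica rara", home, random_seq(600))

    out_records = pd.concat([records, pd.DataFrame(new_rows)], ignore_index=True)
    truth = dict(world.truth)
    truth = json.loads(json.dumps(truth))  # deep copy via JSON round-trip
    truth["pathologies"] = {
        "too_long": n_too_long,
        "too_short": n_too_short,
        "ungeoreferenced": n_ungeoreferenced,
        "invasive": 6,
        "end_gap_retained": n_end_gap,
        "low_copy_records": 2,
        "low_copy_otu": "BOLD:PTLOWCP",
        "end_gap_otu": endgap_otu,
        "invasive_otu": "BOLD:PTINVAS",
    }
    return WorldData(
        records=out_records,
        alignments=world.alignments,
        env=world.env,
        truth=truth,
        invasive_list={invasive_species},
    )


def write_world(world: WorldData, outdir: str | Path) -> dict[str, Path]:
    """Write a world to disk: records.tsv, env.csv, truth.json, invasive.csv
    and per-OTU-per-cell FASTA files under fasta/."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.tsv",
        "env": outdir / "env.csv",
        "truth": outdir / "truth.json",
        "fasta_dir": outdir / "fasta",
        "invasive": outdir / "invasive.csv",
    }
    world.records.to_csv(paths["records"], sep="\t", index=False)
    world.env.to_csv(paths["env"])
    with open(paths["truth"], "w") as fh:
        json.dump(world.truth, fh, indent=1, sort_keys=True)
    paths["fasta_dir"].mkdir(exist_ok=True)
    for (cell, otu), seqs in sorted(world.alignments.items()):
        safe = otu.replace(":", "_")
        bold_io.write_fasta(
            {f"{otu}_{i}": s for i, s in enumerate(seqs)},
            paths["fasta_dir"] / f"{cell}__{safe}.fasta",
        )
    pd.DataFrame({"taxon": sorted(world.invasive_list), "source": "synthetic"}).to_csv(
        paths["invasive"], index=False
    )
    return paths


# ---------------------------------------------------------------------------
# cell-level worlds for regression tests


@dataclass
class CellWorld:
    """A cell-level planted regression world (no sequences)."""

    X: pd.DataFrame
    y: np.ndarray
    coords: np.ndarray
    signal: np.ndarray  # planted noiseless cell value (X beta + field)
    slopes: np.ndarray
    field: np.ndarray
    noise_sd: float


def simulate_cell_world(
    n_cells: int = 200,
    slopes=(0.5, -0.3, 0.0),
    intercept: float = 0.0,
    field_sd: float = 0.25,
    field_range: float = 800_000.0,
    noise_sd: float = 0.1,
    extent: float = 4_000_000.0,
    seed: int | None = None,
) -> CellWorld:
    """Cell-level world: standardized predictors, spatial field, iid noise.

    Used for parameter-recovery and selection experiments where the
    sequence layer is irrelevant: y = intercept + X beta + w + eps with w a
    Gaussian field (exponential covariance, sd ``field_sd``, range
    ``field_range`` meters) over uniformly scattered cells in an
    ``extent``-sized square.
    """
    rng = np.random.default_rng(seed)
    slopes = np.asarray(slopes, dtype=float)
    p = slopes.size
    coords = rng.uniform(0, extent, size=(n_cells, 2))
    x = rng.standard_normal((n_cells, p))
    w = field_sd * _gp_field(coords, field_range, rng)
    signal = intercept + x @ slopes + w
    y = signal + noise_sd * rng.standard_normal(n_cells)
    cols = [f"x{i + 1}" for i in range(p)]
    return CellWorld(
        X=pd.DataFrame(x, columns=cols),
        y=y,
        coords=coords,
        signal=signal,
        slopes=slopes,
        field=w,
        noise_sd=noise_sd,
    )
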