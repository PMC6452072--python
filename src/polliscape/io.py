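"""Domain types and delimited-text I/O for site--pollinator visitation surveys.

The observational unit is one row per (site, visitor species) with a total
visit count, plus site metadata (land-use category and coordinates).  Sites
form the lower level and visitor species the higher level of a weighted
bipartite network; the incidence matrix built here carries the marginal
totals every downstream metric (d', strength, modularity, null models) is
defined against.

Plant reproduction is recorded per individual sentinel plant (unfertilized
flowers, fertilized pods, seeds per pod) and standardized per site to the
proportion of fertilized pods and the number of seeds per pod, with
sampling variances used as regression weights downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("polliscape")

#: canonical land-use categories of the study landscape (extensible: readers
#: accept any non-empty label, these are just the defaults used throughout)
LAND_USES = ("forest", "avocado", "dairy", "potato")

VISITATION_COLUMNS = [
    "site_id",
    "land_use",
    "latitude",
    "longitude",
    "species_id",
    "order_name",
    "family_name",
    "visits",
]

PLANT_COLUMNS = [
    "site_id",
    "plant_id",
    "n_inflorescences",
    "n_unfertilized_flowers",
    "n_pods",
    "seeds",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


# ---------------------------------------------------------------------------
# visitation records


@dataclass(frozen=True)
class VisitationRecord:
    """One aggregated observation: total visits of one species at one site."""

    site_id: str
    land_use: str
    latitude: float
    longitude: float
    species_id: str
    order_name: str
    visits: int
    family_name: str | None = None

    def __post_init__(self) -> None:
        if self.visits < 0:
            raise ValidationError(
                f"negative visit count {self.visits} for ({self.site_id}, {self.species_id})"
            )


@dataclass
class VisitationTable:
    """Validated, duplicate-aggregated long-format visitation data.

    ``records`` holds one row per (site_id, species_id) with columns
    :data:`VISITATION_COLUMNS`; each site has exactly one land use and one
    coordinate pair.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = _validate_visitation_frame(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sites(self) -> pd.DataFrame:
        """One row per site: site_id, land_use, latitude, longitude."""
        return (
            self.records[["site_id", "land_use", "latitude", "longitude"]]
            .drop_duplicates("site_id")
            .reset_index(drop=True)
        )

    @property
    def species(self) -> pd.DataFrame:
        """One row per species: species_id, order_name, family_name."""
        return (
            self.records[["species_id", "order_name", "family_name"]]
            .drop_duplicates("species_id")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records: Iterable[VisitationRecord]) -> "VisitationTable":
        rows = [
            {
                "site_id": r.site_id,
                "land_use": r.land_use,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "species_id": r.species_id,
                "order_name": r.order_name,
                "family_name": r.family_name,
                "visits": r.visits,
            }
            for r in records
        ]
        if not rows:
            raise ValidationError("empty visitation record collection")
        return cls(pd.DataFrame(rows))

    def to_csv(self, path: str | Path, sep: str = ",") -> Path:
        path = Path(path)
        self.records.to_csv(path, sep=sep, index=False)
        return path


def _validate_visitation_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VISITATION_COLUMNS if c != "family_name" and c not in df.columns]
    if missing:
        raise SchemaError(f"visitation table missing required column(s): {', '.join(missing)}")
    df = df.copy()
    if "family_name" not in df.columns:
        df["family_name"] = None
    if df.empty:
        raise ValidationError("visitation table has no rows")

    visits = pd.to_numeric(df["visits"], errors="coerce")
    bad = df.index[visits.isna() | (visits < 0) | (visits != visits.round())]
    if len(bad):
        raise ValidationError(
            f"invalid (negative, missing or non-integer) visit count at row(s) {list(bad[:5])}"
        )
    df["visits"] = visits.astype(int)
    for col in ("latitude", "longitude"):
        df[col] = pd.to_numeric(df[col], errors="raise")

    # one land use + one coordinate pair per site
    meta = df[["site_id", "land_use", "latitude", "longitude"]].drop_duplicates()
    dup_sites = meta["site_id"][meta["site_id"].duplicated()].unique()
    if len(dup_sites):
        raise ValidationError(
            f"site(s) with conflicting land use or coordinates: {', '.join(map(str, dup_sites))}"
        )

    n_dup = df.duplicated(["site_id", "species_id"]).sum()
    if n_dup:
        logger.info("summing %d duplicate (site, species) visitation rows", n_dup)
        df = (
            df.groupby(
                ["site_id", "land_use", "latitude", "longitude", "species_id", "order_name"],
                dropna=False,
                sort=False,
            )
            .agg(family_name=("family_name", "first"), visits=("visits", "sum"))
            .reset_index()
        )
    return df[VISITATION_COLUMNS].reset_index(drop=True)


def read_visitation(path: str | Path, dialect: str = ",") -> VisitationTable:
    """Read a long-format visitation CSV/TSV into a validated table.

    Duplicate (site, species) rows are summed with a logged message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect)
    return VisitationTable(df)


# ---------------------------------------------------------------------------
# incidence matrix


@dataclass
class IncidenceMatrix:
    """Weighted bipartite incidence matrix: rows = sites, columns = species.

    Carries marginal totals: ``K`` (row totals), ``L`` (column totals) and the
    grand total ``F`` with the identity sum(K) == sum(L) == F.
    """

    A: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    row_meta: pd.DataFrame | None = None  # site metadata aligned to row_labels
    col_meta: pd.DataFrame | None = None  # species metadata aligned to col_labels

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValidationError("incidence matrix must be 2-dimensional")
        if self.A.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("matrix shape does not match label lengths")
        if (self.A < 0).any():
            raise ValidationError("incidence matrix has negative weights")

    @property
    def K(self) -> np.ndarray:
        return self.A.sum(axis=1)

    @property
    def L(self) -> np.ndarray:
        return self.A.sum(axis=0)

    @property
    def F(self) -> float:
        return float(self.A.sum())

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_cols(self) -> int:
        return self.A.shape[1]

    @property
    def n_links(self) -> int:
        """Number of nonzero cells (realized site-species links)."""
        return int(np.count_nonzero(self.A))

    def row_index(self, site_id: str) -> int:
        return self.row_labels.index(site_id)

    def col_index(self, species_id: str) -> int:
        return self.col_labels.index(species_id)

    def with_weights(self, A: np.ndarray) -> "IncidenceMatrix":
        """Same labels/metadata, new weight matrix (used by null models)."""
        return IncidenceMatrix(
            A=np.asarray(A, dtype=float),
            row_labels=list(self.row_labels),
            col_labels=list(self.col_labels),
            row_meta=self.row_meta,
            col_meta=self.col_meta,
        )


def build_matrix(table: VisitationTable) -> IncidenceMatrix:
    """Pivot a visitation table into a weighted incidence matrix.

    Sites or species whose total visits are zero are dropped with a logged
    warning: d', the null models and the module search are undefined for
    zero-margin nodes.
    """
    if len(table) == 0:
        raise ValidationError("cannot build a matrix from an empty table")
    wide = table.records.pivot_table(
        index="site_id", columns="species_id", values="visits", aggfunc="sum", fill_value=0
    )
    # preserve first-appearance order rather than pandas' lexicographic sort
    site_order = table.records["site_id"].drop_duplicates().tolist()
    sp_order = table.records["species_id"].drop_duplicates().tolist()
    wide = wide.reindex(index=site_order, columns=sp_order, fill_value=0)

    A = wide.to_numpy(dtype=float)
    keep_rows = A.sum(axis=1) > 0
    keep_cols = A.sum(axis=0) > 0
    if not keep_rows.all():
        dropped = [s for s, k in zip(wide.index, keep_rows) if not k]
        logger.warning("dropping %d zero-visit site(s): %s", len(dropped), dropped)
    if not keep_cols.all():
        dropped = [s for s, k in zip(wide.columns, keep_cols) if not k]
        logger.warning("dropping %d zero-visit species: %s", len(dropped), dropped)
    A = A[keep_rows][:, keep_cols]
    row_labels = [s for s, k in zip(wide.index, keep_rows) if k]
    col_labels = [s for s, k in zip(wide.columns, keep_cols) if k]

    sites = table.sites.set_index("site_id").loc[row_labels].reset_index()
    species = table.species.set_index("species_id").loc[col_labels].reset_index()
    return IncidenceMatrix(A, row_labels, col_labels, row_meta=sites, col_meta=species)


# ---------------------------------------------------------------------------
# plant reproduction


@dataclass(frozen=True)
class PlantRecord:
    """Reproductive output of one sentinel plant at one site."""

    site_id: str
    plant_id: str
    n_inflorescences: int
    n_unfertilized_flowers: int
    n_pods: int
    seeds_per_pod: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = (self.n_inflorescences, self.n_unfertilized_flowers, self.n_pods)
        if any(c < 0 for c in counts) or any(s < 0 for s in self.seeds_per_pod):
            raise ValidationError(f"negative count in plant record {self.plant_id}")
        if len(self.seeds_per_pod) != self.n_pods:
            raise ValidationError(
                f"plant {self.plant_id}: {len(self.seeds_per_pod)} seed counts for {self.n_pods} pods"
            )

    @property
    def fert_prop(self) -> float:
        """Fertilized-pod proportion: pods / (unfertilized flowers + pods)."""
        denom = self.n_unfertilized_flowers + self.n_pods
        if denom == 0:
            raise ValidationError(f"plant {self.plant_id} has no scored flowers")
        return self.n_pods / denom


@dataclass(frozen=True)
class SiteReproduction:
    """Per-site mean and sample variance of the two reproduction measures.

    ``var_seeds`` pools all pods at the site; ``var_seeds_plant`` is the
    variance of plant-level mean seed counts (both are computed because the
    weighting convention is a modelling choice; pooled is the default used
    downstream).
    """

    site_id: str
    mean_fert_prop: float
    var_fert_prop: float
    mean_seeds: float
    var_seeds: float
    n_plants: int
    var_seeds_plant: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_fert_prop <= 1.0):
            raise ValidationError(f"mean fertilized proportion outside [0,1] at {self.site_id}")
        if self.var_fert_prop < 0 or self.var_seeds < 0:
            raise ValidationError(f"negative variance at {self.site_id}")


def _sample_var(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.var(x, ddof=1)) if x.size > 1 else 0.0


def standardize_reproduction(plants: Sequence[PlantRecord]) -> list[SiteReproduction]:
    """Standardize plant-level reproduction to per-site means and variances.

    Plants with no scored flowers (unfertilized + pods == 0) are excluded with
    a warning; a site with zero valid plants is excluded entirely.
    """
    by_site: dict[str, list[PlantRecord]] = {}
    for p in plants:
        by_site.setdefault(p.site_id, []).append(p)

    out: list[SiteReproduction] = []
    for site_id, site_plants in by_site.items():
        valid = [p for p in site_plants if p.n_unfertilized_flowers + p.n_pods > 0]
        n_excluded = len(site_plants) - len(valid)
        if n_excluded:
            logger.warning("site %s: excluding %d plant(s) with no scored flowers", site_id, n_excluded)
        if not valid:
            logger.warning("site %s: no valid plants, excluded from reproduction summaries", site_id)
            continue
        props = np.array([p.fert_prop for p in valid])
        pooled_seeds = np.concatenate([np.asarray(p.seeds_per_pod, dtype=float) for p in valid]) \
            if any(p.n_pods for p in valid) else np.array([])
        plant_means = np.array([np.mean(p.seeds_per_pod) for p in valid if p.n_pods > 0])
        out.append(
            SiteReproduction(
                site_id=site_id,
                mean_fert_prop=float(props.mean()),
                var_fert_prop=_sample_var(props),
                mean_seeds=float(pooled_seeds.mean()) if pooled_seeds.size else 0.0,
                var_seeds=_sample_var(pooled_seeds),
                n_plants=len(valid),
                var_seeds_plant=_sample_var(plant_means) if plant_means.size else 0.0,
            )
        )
    return out


def read_plants(path: str | Path, dialect: str = ",") -> list[PlantRecord]:
    """Read a plants CSV (seeds as a semicolon-joined list, one entry per pod)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect, dtype={"seeds": str})
    missing = [c for c in PLANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plants table missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        raw = row["seeds"]
        if pd.isna(raw) or str(raw).strip() == "":
            seeds: tuple[int, ...] = ()
        else:
            try:
                seeds = tuple(int(s) for s in str(raw).split(";"))
            except ValueError as exc:
                raise ValidationError(f"row {idx}: malformed seeds list {raw!r}") from exc
        try:
            records.append(
                PlantRecord(
                    site_id=str(row["site_id"]),
                    plant_id=str(row["plant_id"]),
                    n_inflorescences=int(row["n_inflorescences"]),
                    n_unfertilized_flowers=int(row["n_unfertilized_flowers"]),
                    n_pods=int(row["n_pods"]),
                    seeds_per_pod=seeds,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return records


def write_plants(plants: Sequence[PlantRecord], path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    rows = [
        {
            "site_id": p.site_id,
            "plant_id": p.plant_id,
            "n_inflorescences": p.n_inflorescences,
            "n_unfertilized_flowers": p.n_unfertilized_flowers,
            "n_pods": p.n_pods,
            "seeds": ";".join(map(str, p.seeds_per_pod)),
        }
        for p in plants
    ]
    pd.DataFrame(rows, columns=PLANT_COLUMNS).to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class SAParams:
    """Simulated-annealing schedule for the module search.

    ``steps_per_temperature`` of None means ``moves_per_node`` moves per node
    per sweep; the temperature is multiplied by ``cooling`` after every sweep
    and one annealing run stops after ``patience`` sweeps without improvement
    (or ``max_sweeps``).  The search runs ``restarts`` independent annealings
    and keeps the best partition: the warm phase of a single chain is a
    random walk that can strand the best-seen partition at a mediocre value,
    and restarts are the cheap, standard insurance against that.
    """

    t0: float = 0.02
    cooling: float = 0.98
    moves_per_node: float = 50.0  # used when steps_per_temperature is None
    steps_per_temperature: int | None = None
    max_sweeps: int = 2000
    patience: int = 200
    restarts: int = 4

    def steps_for(self, n_nodes: int) -> int:
        if self.steps_per_temperature is not None:
            return int(self.steps_per_temperature)
        return max(1, int(self.moves_per_node * n_nodes))

    def scaled(self, factor: float) -> "SAParams":
        """A schedule whose total move budget is scaled by ``factor``.

        Moves per sweep shrink by ``factor`` and cooling accelerates by the
        same factor (``cooling**(1/factor)``), so the reduced-budget search
        still anneals to low temperature instead of stopping warm.
        """
        steps = self.steps_per_temperature
        return SAParams(
            t0=self.t0,
            cooling=self.cooling ** (1.0 / factor),
            moves_per_node=max(1.0, self.moves_per_node * factor),
            steps_per_temperature=None if steps is None else max(1, int(steps * factor)),
            max_sweeps=self.max_sweeps,
            patience=self.patience,
            restarts=self.restarts,
        )


#: budget factor applied to null-ensemble module searches when fast_null is on
FAST_NULL_FACTOR = 0.25


@dataclass
class RunConfig:
    """Knobs of a full analysis run; every field is recorded in the summary."""

    random_seed: int = 0
    n_null: int = 100
    sa_params: SAParams = field(default_factory=SAParams)
    threshold_quantile: float = 0.975
    weight_scheme: str = "variance"  # or "inverse_variance"
    fast_null: bool = False
    dmax_unconstrained: bool = False
    binary_roles: bool = False

    def __post_init__(self) -> None:
        if self.n_null < 2:
            raise ValidationError("n_null must be at least 2")
        if not (0.0 < self.threshold_quantile < 1.0):
            raise ValidationError("threshold_quantile must be in (0, 1)")
        if self.weight_scheme not in ("variance", "inverse_variance"):
            raise ValidationError(f"unknown weight scheme {self.weight_scheme!r}")

    def null_sa_params(self) -> SAParams:
        return self.sa_params.scaled(FAST_NULL_FACTOR) if self.fast_null else self.sa_params


# ---------------------------------------------------------------------------
# output writing


def write_outputs(
    out_dir: str | Path,
    node_metrics: pd.DataFrame,
    partition: pd.DataFrame,
    null_summary: pd.DataFrame,
    models: pd.DataFrame,
    run_summary: Mapping,
) -> dict[str, Path]:
    """Write the standard artifact set as delimited text plus a JSON summary.

    Floats round-trip through ``repr`` so re-reading reproduces integers
    bit-exactly and reals to well beyond 12 significant digits.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths = {
        "node_metrics": out_dir / "node_metrics.csv",
        "partition": out_dir / "partition.csv",
        "null_summary": out_dir / "null_summary.csv",
        "models": out_dir / "models.csv",
        "run_summary": out_dir / "run_summary.json",
    }
    node_metrics.to_csv(paths["node_metrics"], index=False)
    partition.to_csv(paths["partition"], index=False)
    null_summary.to_csv(paths["null_summary"], index=False)
    models.to_csv(paths["models"], index=False)
    with open(paths["run_summary"], "w") as fh:
        json.dump(_jsonable(run_summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
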