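"""Raw intensity -> analysis-ready marker values.

The multiplexed-immunofluorescence chain quantifies each marker as a raw
median fluorescence intensity per cell compartment, acquired at a per-round
exposure time.  Analysis values are produced by:

1. exposure correction to a per-round nominal (reference) exposure,
2. ``log2(x + 1)`` variance stabilisation,
3. per-slide median centring to remove slide batch effects,
4. choosing the nuclear-median or whole-cell-median readout per marker,
5. (clustering markers only) capping the 1% tails and z-standardising.

Steps 1-2 are applied to both compartment readouts, step 4 keeps one of
them, step 3 operates on the kept value.  All transforms before
standardisation are strictly monotone per marker, so the within-marker rank
order of cells is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDataError

logger = logging.getLogger(__name__)

NUCLEAR_MARKERS = ("ER", "PR", "p21", "Ki67")
CLUSTERING_MARKERS = ("ER", "HER2", "cMET", "SLC7A5")

SUMMARIZATIONS = ("nuclear_median", "cell_median")
ROLES = ("clustering", "univariate_only", "segmentation_only", "excluded")


@dataclass(frozen=True)
class MarkerSpec:
    """One marker of the staining panel."""

    name: str
    round: int
    summarization: str  # nuclear_median | cell_median
    role: str  # clustering | univariate_only | segmentation_only | excluded
    reference_exposure_ms: float = 50.0

    def __post_init__(self):
        if self.summarization not in SUMMARIZATIONS:
            raise DataError(f"marker {self.name}: unknown summarization "
                            f"{self.summarization!r}")
        if self.role not in ROLES:
            raise DataError(f"marker {self.name}: unknown role {self.role!r}")
        if self.reference_exposure_ms <= 0:
            raise DataError(f"marker {self.name}: reference exposure must be > 0")


@dataclass
class MarkerPanel:
    """Marker -> (staining round, summarization, analysis role) mapping."""

    markers: list[MarkerSpec]

    def __post_init__(self):
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise DataError("duplicate marker names in panel")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self):
        return len(self.markers)

    def get(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise DataError(f"marker {name!r} not in panel")

    @property
    def analysis_markers(self) -> list[str]:
        """Markers carried into statistics (clustering + univariate)."""
        return [m.name for m in self.markers
                if m.role in ("clustering", "univariate_only")]

    @property
    def clustering_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.role == "clustering"]

    @property
    def rounds(self) -> list[int]:
        return sorted({m.round for m in self.markers})

    def reference_exposure(self, round_: int) -> float:
        for m in self.markers:
            if m.round == round_:
                return m.reference_exposure_ms
        raise DataError(f"no marker in round {round_}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.name, m.round, m.summarization, m.role, m.reference_exposure_ms)
             for m in self.markers],
            columns=["marker", "round", "summarization", "role",
                     "reference_exposure_ms"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        required = {"marker", "round", "summarization", "role"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"panel file missing columns: {sorted(missing)}")
        specs = []
        for _, row in df.iterrows():
            specs.append(MarkerSpec(
                name=str(row["marker"]),
                round=int(row["round"]),
                summarization=str(row["summarization"]),
                role=str(row["role"]),
                reference_exposure_ms=float(row.get("reference_exposure_ms", 50.0)),
            ))
        return cls(specs)

    @classmethod
    def from_csv(cls, path) -> "MarkerPanel":
        return cls.from_frame(pd.read_csv(path))


#: Background (non-clustering) markers available to the simulator, with the
#: staining round each was acquired in.
BACKGROUND_MARKER_ROUNDS = (
    ("p53", 8), ("COX2", 9), ("CD44v6", 7), ("CDCP1", 8),
    ("CK15", 9), ("MRP4", 12), ("HTF9C", 11), ("VEGFR2", 10),
)


def default_panel(n_background: int = 4) -> MarkerPanel:
    """The default analysis panel.

    ER, PR, p21 and Ki67 are nuclear markers read out as median nuclear
    intensity; everything else uses the whole-cell median.  The clustering
    set is ER/HER2/cMET/SLC7A5.  EGFR is carried in the panel but excluded
    from analysis (weak, inconsistent staining).
    """
    if not 0 <= n_background <= len(BACKGROUND_MARKER_ROUNDS):
        raise DataError("n_background out of range")

    def summ(name):
        return "nuclear_median" if name in NUCLEAR_MARKERS else "cell_median"

    specs = [
        MarkerSpec("ER", 4, "nuclear_median", "clustering"),
        MarkerSpec("PR", 4, "nuclear_median", "univariate_only"),
        MarkerSpec("cMET", 6, "cell_median", "clustering"),
        MarkerSpec("HER2", 7, "cell_median", "clustering"),
        MarkerSpec("SLC7A5", 12, "cell_median", "clustering"),
        MarkerSpec("p21", 13, "nuclear_median", "univariate_only"),
        MarkerSpec("Ki67", 15, "nuclear_median", "univariate_only"),
        MarkerSpec("EGFR", 13, "cell_median", "excluded"),
    ]
    for name, rnd in BACKGROUND_MARKER_ROUNDS[:n_background]:
        specs.append(MarkerSpec(name, rnd, summ(name), "univariate_only"))
    return MarkerPanel(specs)


# ---------------------------------------------------------------------------
# elementary transforms


def exposure_correct(raw, exposure_ms, reference_ms):
    """Rescale raw intensity to the reference exposure time.

    Fluorescence response is assumed linear in exposure, so
    ``corrected = raw * reference_ms / exposure_ms``.
    """
    raw = np.asarray(raw, dtype=float)
    exposure_ms = np.asarray(exposure_ms, dtype=float)
    if np.any(exposure_ms <= 0):
        raise DataError("exposure_ms must be > 0")
    if np.any(np.asarray(reference_ms, dtype=float) <= 0):
        raise DataError("reference_ms must be > 0")
    return raw * (np.asarray(reference_ms, dtype=float) / exposure_ms)


def log_transform(corrected, offset: float = 1.0):
    """``log2(x + offset)`` with a pseudo-count to keep zero intensities finite."""
    if offset <= 0:
        raise DataError("log offset must be > 0")
    return np.log2(np.asarray(corrected, dtype=float) + offset)


def normalize_slides(values: pd.DataFrame, slide_ids: pd.Series) -> pd.DataFrame:
    """Remove slide batch effects by per-slide median centring.

    Per marker and slide the slide median is subtracted and the grand
    median (over all cells) added back, so after normalisation every
    slide's median equals the grand median.  Rank order within a slide is
    preserved.
    """
    slide_ids = pd.Series(slide_ids).reindex(values.index)
    if slide_ids.isna().any():
        raise DataError("slide id missing for some cells")
    out = values.copy()
    grand = values.median(axis=0)
    slide_medians = values.groupby(slide_ids, observed=True).transform("median")
    out = values - slide_medians + grand
    return out


def summarize_cells(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Pick one readout per analysis marker per cell.

    Nuclear markers (ER, PR, p21, Ki67) use the ``<marker>_nuclear_median``
    column, the rest ``<marker>_cell_median``; excluded and
    segmentation-only markers are dropped.
    """
    out = {}
    for spec in panel:
        if spec.role not in ("clustering", "univariate_only"):
            continue
        compartment = "nuclear" if spec.summarization == "nuclear_median" else "cell"
        col = f"{spec.name}_{compartment}_median"
        if col not in cells.columns:
            raise DataError(f"marker {spec.name}: column {col!r} missing")
        out[spec.name] = cells[col].to_numpy(dtype=float)
    return pd.DataFrame(out, index=cells.index)


@dataclass
class CapStandardizeParams:
    """Frozen 1%-capping bounds and z-scaling for one marker column."""

    lower: float
    upper: float
    mean: float
    sd: float

    def transform(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.lower, self.upper)
        return (x - self.mean) / self.sd


def cap_and_standardize(values, tail: float = 0.01):
    """Cap the 1% tails and z-standardise one column.

    Percentiles use the linear-interpolation quantile convention.  The mean
    and sd are computed after capping, so the output has mean 0 and sd 1
    (population sd).  Returns ``(standardised array, CapStandardizeParams)``.
    """
    x = np.asarray(values, dtype=float)
    if not 0 <= tail < 0.5:
        raise DataError("tail must be in [0, 0.5)")
    if np.unique(x).size < 2:
        raise DegenerateDataError("constant column: cannot standardise (sd = 0)")
    lower, upper = np.quantile(x, [tail, 1.0 - tail], method="linear")
    capped = np.clip(x, lower, upper)
    mean = capped.mean()
    sd = capped.std()
    if sd == 0:
        raise DegenerateDataError("column constant after capping (sd = 0)")
    params = CapStandardizeParams(lower=float(lower), upper=float(upper),
                                  mean=float(mean), sd=float(sd))
    return (capped - mean) / sd, params


@dataclass
class NormalizedMatrix:
    """Analysis-ready per-cell marker values with frozen transform parameters.

    ``values`` holds log2, exposure-corrected, slide-normalised summarised
    intensities (one column per analysis marker).  ``z`` holds the capped
    and standardised clustering-marker columns.  The stored parameters
    reproduce the z-transform on held-out cells via :meth:`transform_z`.
    """

    values: pd.DataFrame
    z: pd.DataFrame
    params: dict[str, CapStandardizeParams] = field(default_factory=dict)
    clustering_markers: list[str] = field(default_factory=list)

    def transform_z(self, values: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for marker in self.clustering_markers:
            out[marker] = self.params[marker].transform(values[marker])
        return pd.DataFrame(out, index=values.index)

    def params_dict(self) -> dict:
        return {m: vars(p) for m, p in self.params.items()}


def preprocess_cells(cells: pd.DataFrame, panel: MarkerPanel,
                     log2_offset: float = 1.0,
                     tail: float = 0.01) -> NormalizedMatrix:
    """Run the full preprocessing chain on a post-QC cell table.

    Expects raw intensity columns ``<marker>_nuclear_median`` /
    ``<marker>_cell_median``, per-round exposure columns
    ``exposure_r<round>_ms`` and a ``slide_id`` column.  Standardisation
    parameters are fitted on the cells given here and frozen in the result.
    """
    if "slide_id" not in cells.columns:
        raise DataError("cell table lacks slide_id")
    summarized = {}
    for spec in panel:
        if spec.role not in ("clustering", "univariate_only"):
            continue
        compartment = "nuclear" if spec.summarization == "nuclear_median" else "cell"
        col = f"{spec.name}_{compartment}_median"
        expo_col = f"exposure_r{spec.round}_ms"
        if col not in cells.columns:
            raise DataError(f"marker {spec.name}: column {col!r} missing")
        if expo_col not in cells.columns:
            raise DataError(f"marker {spec.name}: column {expo_col!r} missing")
        corrected = exposure_correct(cells[col], cells[expo_col],
                                     spec.reference_exposure_ms)
        summarized[spec.name] = log_transform(corrected, log2_offset)
    values = pd.DataFrame(summarized, index=cells.index)
    values = normalize_slides(values, cells["slide_id"])

    clustering = [m for m in panel.clustering_markers if m in values.columns]
    z_cols, params = {}, {}
    for marker in clustering:
        z_cols[marker], params[marker] = cap_and_standardize(values[marker], tail)
    z = pd.DataFrame(z_cols, index=values.index)
    return NormalizedMatrix(values=values, z=z, params=params,
                            clustering_markers=clustering)
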