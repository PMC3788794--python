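"""Detection-history and patch-covariate data model and I/O.

A study consists of a set of habitat patches, each surveyed ``n_surveys``
times per season over ``n_seasons`` seasons.  Every survey yields a binary
detection (1 = the species was seen, 0 = it was not), with missing surveys
allowed.  Each patch additionally carries five habitat characteristics:
size, composition, vegetation cover, surrounding matrix type, and isolation
(Euclidean distance in metres to the nearest neighbouring patch).

Detection histories are stored internally as a float array of shape
``(n_patches, n_seasons, n_surveys)`` with ``NaN`` marking missing surveys;
covariates live in a :class:`pandas.DataFrame` indexed by patch id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError, UndefinedValueError

SIZE_LEVELS = ("small", "medium", "large")
COMPOSITION_LEVELS = ("clustered", "discrete")
VEGETATION_LEVELS = ("none", "moderate", "abundant")
MATRIX_LEVELS = ("pasture", "tussock")

COVARIATE_COLUMNS = ("size", "composition", "vegetation", "matrix", "isolation_m")

_CATEGORY_LEVELS = {
    "size": SIZE_LEVELS,
    "composition": COMPOSITION_LEVELS,
    "vegetation": VEGETATION_LEVELS,
    "matrix": MATRIX_LEVELS,
}


@dataclass(frozen=True)
class PatchCovariates:
    """Habitat characteristics of a single patch."""

    patch_id: str
    size: str
    composition: str
    vegetation: str
    matrix: str
    isolation_m: float

    def __post_init__(self) -> None:
        for name in ("size", "composition", "vegetation", "matrix"):
            value = getattr(self, name)
            if value not in _CATEGORY_LEVELS[name]:
                raise ParseError(
                    f"patch {self.patch_id!r}: unknown {name} level {value!r}; "
                    f"expected one of {_CATEGORY_LEVELS[name]}"
                )
        if not np.isfinite(self.isolation_m) or self.isolation_m < 0:
            raise ParseError(
                f"patch {self.patch_id!r}: isolation_m must be a nonnegative "
                f"number, got {self.isolation_m!r}"
            )


@dataclass
class SurveyHistory:
    """One patch's detections: array of shape (n_seasons, n_surveys), NaN = missing."""

    patch_id: str
    detections: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.detections, dtype=float)
        if arr.ndim != 2:
            raise ParseError(
                f"patch {self.patch_id!r}: detections must be 2-d (seasons x surveys)"
            )
        finite = arr[~np.isnan(arr)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ParseError(
                f"patch {self.patch_id!r}: detections must be 0, 1 or missing"
            )
        self.detections = arr

    @property
    def n_seasons(self) -> int:
        return self.detections.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.detections.shape[1]


class MetapopDataset:
    """Aligned detection histories and covariates for a patch network.

    Parameters
    ----------
    detections
        Float array ``(n_patches, n_seasons, n_surveys)``; NaN = missing.
    covariates
        DataFrame indexed by patch id with columns
        ``size, composition, vegetation, matrix, isolation_m``.
    patch_ids
        Patch identifiers in the order of the detection array's first axis.
    """

    def __init__(
        self,
        patch_ids: list[str],
        detections: np.ndarray,
        covariates: pd.DataFrame,
    ) -> None:
        detections = np.asarray(detections, dtype=float)
        if detections.ndim != 3 or detections.shape[0] != len(patch_ids):
            raise AlignmentError("detections must be (n_patches, n_seasons, n_surveys)")
        finite = detections[~np.isnan(detections)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ParseError("detections must be 0, 1 or missing")
        if len(set(patch_ids)) != len(patch_ids):
            raise AlignmentError("duplicate patch ids")
        missing = set(patch_ids) - set(covariates.index)
        extra = set(covariates.index) - set(patch_ids)
        if missing or extra:
            raise AlignmentError(
                f"patch ids do not align: {sorted(missing)[:5]} lack covariates, "
                f"{sorted(extra)[:5]} lack histories"
            )
        self.patch_ids = [str(p) for p in patch_ids]
        self.detections = detections
        self.covariates = covariates.loc[self.patch_ids, list(COVARIATE_COLUMNS)]
        # validate every covariate row
        for pid, row in self.covariates.iterrows():
            PatchCovariates(str(pid), *row[list(COVARIATE_COLUMNS[:-1])], float(row.isolation_m))

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    @property
    def n_seasons(self) -> int:
        return self.detections.shape[1]

    @property
    def n_surveys(self) -> int:
        return self.detections.shape[2]

    def history(self, patch_id: str) -> SurveyHistory:
        idx = self.patch_ids.index(patch_id)
        return SurveyHistory(patch_id, self.detections[idx])

    def covariate(self, patch_id: str) -> PatchCovariates:
        row = self.covariates.loc[patch_id]
        return PatchCovariates(
            patch_id, row["size"], row["composition"], row["vegetation"],
            row["matrix"], float(row["isolation_m"]),
        )

    def subset(self, indices: np.ndarray) -> "MetapopDataset":
        """Dataset restricted to the patches at the given positional indices."""
        ids = [self.patch_ids[i] for i in np.asarray(indices, dtype=int)]
        return MetapopDataset(ids, self.detections[np.asarray(indices, dtype=int)],
                              self.covariates.loc[ids])

    def to_csv(self, histories_path, covariates_path) -> None:
        """Write the long-format histories CSV and the covariates CSV."""
        rows = []
        for i, pid in enumerate(self.patch_ids):
            for t in range(self.n_seasons):
                for j in range(self.n_surveys):
                    y = self.detections[i, t, j]
                    rows.append(
                        (pid, t + 1, j + 1, "" if np.isnan(y) else int(y))
                    )
        pd.DataFrame(rows, columns=["patch_id", "season", "survey", "detection"]).to_csv(
            histories_path, index=False
        )
        self.covariates.rename_axis("patch_id").to_csv(covariates_path)


def _parse_detection(value, row: int) -> float:
    if pd.isna(value) or (isinstance(value, str) and value.strip() == ""):
        return np.nan
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}, column 'detection': cannot parse {value!r}") from None
    if v not in (0.0, 1.0):
        raise ParseError(f"row {row}, column 'detection': value {value!r} is not 0/1/missing")
    return v


def load_dataset(histories_path, covariates_path) -> MetapopDataset:
    """Read the two study CSVs and return an aligned dataset.

    The histories file is long-format with header
    ``patch_id,season,survey,detection`` (season and survey 1-based,
    detection empty for a missing survey); the covariates file has header
    ``patch_id,size,composition,vegetation,matrix,isolation_m``.
    """
    hist = pd.read_csv(histories_path, dtype={"patch_id": str})
    required = {"patch_id", "season", "survey", "detection"}
    if not required.issubset(hist.columns):
        raise ParseError(f"histories file must have columns {sorted(required)}")
    cov = pd.read_csv(covariates_path, dtype={"patch_id": str})
    if not {"patch_id", *COVARIATE_COLUMNS}.issubset(cov.columns):
        raise ParseError(
            f"covariates file must have columns ['patch_id', *{list(COVARIATE_COLUMNS)}]"
        )
    cov = cov.set_index("patch_id")

    try:
        seasons = hist["season"].astype(int)
        surveys = hist["survey"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"season/survey columns must be integers: {exc}") from None
    if (seasons < 1).any() or (surveys < 1).any():
        raise ParseError("season and survey indices are 1-based in files")

    patch_ids = list(dict.fromkeys(hist["patch_id"]))
    n_seasons, n_surveys = int(seasons.max()), int(surveys.max())
    det = np.full((len(patch_ids), n_seasons, n_surveys), np.nan)
    index = {p: i for i, p in enumerate(patch_ids)}
    values = [
        _parse_detection(v, r) for r, v in zip(hist.index, hist["detection"])
    ]
    det[[index[p] for p in hist["patch_id"]], seasons - 1, surveys - 1] = values
    return MetapopDataset(patch_ids, det, cov)


def naive_presence(dataset: MetapopDataset, season: int) -> np.ndarray:
    """Per-patch naive status for one season: 1 if any detection, 0 if all
    non-missing surveys are 0, NaN if every survey is missing."""
    if not 0 <= season < dataset.n_seasons:
        raise IndexError(f"season {season} out of range 0..{dataset.n_seasons - 1}")
    y = dataset.detections[:, season, :]
    any_det = np.nansum(y, axis=1) > 0
    all_missing = np.isnan(y).all(axis=1)
    return np.where(all_missing, np.nan, any_det.astype(float))


def naive_occupancy(dataset: MetapopDataset, season: int) -> float:
    """Fraction of (per-season observed) patches with at least one detection.

    Uncorrected for imperfect detection; patches with every survey missing
    that season are excluded from numerator and denominator.
    """
    status = naive_presence(dataset, season)
    observed = ~np.isnan(status)
    if dataset.n_patches == 0 or not observed.any():
        raise UndefinedValueError("naive occupancy undefined: no observed patches")
    return float(np.nansum(status) / observed.sum())


def naive_turnover(
    dataset: MetapopDataset, season_from: int, season_to: int
) -> tuple[int, int]:
    """Counts of naive colonisations and extinctions between two seasons.

    A colonisation is a patch naive-absent in ``season_from`` and
    naive-present in ``season_to``; an extinction is the converse.  Patches
    with an all-missing season at either end are excluded.
    """
    if season_from == season_to:
        raise ValueError("season_from and season_to must differ")
    a = naive_presence(dataset, season_from)
    b = naive_presence(dataset, season_to)
    ok = ~np.isnan(a) & ~np.isnan(b)
    colonisations = int(((a == 0) & (b == 1) & ok).sum())
    extinctions = int(((a == 1) & (b == 0) & ok).sum())
    return colonisations, extinctions
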