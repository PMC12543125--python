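"""Acquisition/reconstruction parameter space of the phantom study.

Nine investigation groups are studied, each varying a single acquisition or
reconstruction parameter while every other parameter is held at a fixed
value: acquisition time per bed, transaxial matrix size, z-axis filter,
post-reconstruction Gaussian filter width, BPL penalisation factor (β),
OSEM update combinations (iterations × subsets), OSEM iterations, OSEM
subsets, and reconstruction algorithm.  The default grid enumerates 94
setting variations in total.

The module also owns the numeric encodings used downstream by the
correction stage: categorical z-axis filters map to their kernel weights
(None→1, Light→2, Standard→4, Heavy→6) and selected groups are rescaled
(×10 or +2) so that reciprocal/logarithmic model forms stay well defined.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd

__all__ = [
    "SettingSpec",
    "InvestigationGroup",
    "GridValidationError",
    "DEFAULT_GROUP_NAMES",
    "build_grid",
    "encode_zfilter",
    "rescale_x",
    "grid_to_frame",
]


class GridValidationError(ValueError):
    """Raised for unknown group names, labels, or out-of-range levels."""


VALID_MATRIX_SIZES = (128, 192, 256, 384)
Z_FILTER_WEIGHTS = {"none": 1.0, "light": 2.0, "standard": 4.0, "heavy": 6.0}
ALGORITHMS = ("OSEM", "TOF-OSEM", "OSEM+PSF", "TOF-OSEM+PSF", "BPL", "TOF-BPL")


@dataclass(frozen=True)
class SettingSpec:
    """One fully specified acquisition/reconstruction setting.

    ``iterations``/``subsets`` may be None only inside the aggregated
    OSEM-iterations / OSEM-subsets groups, whose feature values are means
    over the update combinations rather than separate reconstructions.
    """

    acquisition_time: float = 3.0     # min per bed position
    matrix_size: int = 256            # transaxial dimension
    z_filter: str = "None"            # None | Light | Standard | Heavy
    gaussian_fwhm: float = 5.0        # mm
    algorithm: str = "TOF-OSEM"
    iterations: int | None = 2
    subsets: int | None = 28
    beta: float | None = None         # BPL penalisation factor

    def __post_init__(self) -> None:
        if self.acquisition_time <= 0:
            raise GridValidationError("acquisition_time must be > 0")
        if self.matrix_size not in VALID_MATRIX_SIZES:
            raise GridValidationError(
                f"matrix_size {self.matrix_size} not in {VALID_MATRIX_SIZES}"
            )
        if self.gaussian_fwhm < 0:
            raise GridValidationError("gaussian_fwhm must be >= 0")
        if _norm(self.z_filter) not in Z_FILTER_WEIGHTS:
            raise GridValidationError(f"unknown z_filter label {self.z_filter!r}")
        if _norm_algo(self.algorithm) not in ALGORITHMS:
            raise GridValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.iterations is not None and self.iterations < 1:
            raise GridValidationError("iterations must be >= 1")
        if self.subsets is not None and self.subsets < 1:
            raise GridValidationError("subsets must be >= 1")
        if self.is_bpl and (self.beta is None or self.beta <= 0):
            raise GridValidationError("beta must be > 0 for BPL-type algorithms")

    @property
    def is_bpl(self) -> bool:
        return "BPL" in _norm_algo(self.algorithm)

    @property
    def is_tof(self) -> bool:
        return _norm_algo(self.algorithm).startswith("TOF")

    @property
    def is_psf(self) -> bool:
        return _norm_algo(self.algorithm).endswith("PSF")

    @property
    def updates(self) -> int | None:
        if self.iterations is None or self.subsets is None:
            return None
        return self.iterations * self.subsets


@dataclass(frozen=True)
class InvestigationGroup:
    """A named group varying one SettingSpec field over an ordered level set."""

    name: str
    varied_parameter: str
    levels: tuple
    constants: dict = field(default_factory=dict)
    # feature values of this group are means over this nuisance axis of the
    # update-combination reconstructions (Table-style averaging), or None
    aggregate_over: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise GridValidationError(f"group {self.name}: duplicate levels")


def _norm(label: str) -> str:
    return str(label).strip().lower()


def _norm_algo(label: str) -> str:
    return str(label).strip().upper().replace(" ", "")


def encode_zfilter(label: str) -> float:
    """Map a z-axis filter label to its numeric kernel weight.

    None→1, Light→2, Standard→4, Heavy→6.  Matching is case-insensitive
    after trimming whitespace.
    """
    key = _norm(label)
    if key not in Z_FILTER_WEIGHTS:
        raise GridValidationError(
            f"unknown z-filter label {label!r}; expected one of "
            f"{sorted(Z_FILTER_WEIGHTS)}"
        )
    return Z_FILTER_WEIGHTS[key]


# canonical group names
ACQ_TIME = "acquisition_time"
MATRIX = "matrix_size"
ZFILTER = "z_filter"
GAUSSIAN = "gaussian_filter"
BPL_BETA = "bpl_beta"
OSEM_UPDATES = "osem_updates"
OSEM_ITERATIONS = "osem_iterations"
OSEM_SUBSETS = "osem_subsets"
ALGORITHM = "algorithm"

DEFAULT_GROUP_NAMES = (
    ACQ_TIME,
    MATRIX,
    ZFILTER,
    GAUSSIAN,
    BPL_BETA,
    OSEM_UPDATES,
    OSEM_ITERATIONS,
    OSEM_SUBSETS,
    ALGORITHM,
)

# groups whose x-values are multiplied by 10 before fitting/correction
_RESCALE_X10 = {ACQ_TIME, ZFILTER, OSEM_ITERATIONS}
# groups whose x-values are shifted by +2
_RESCALE_SHIFT2 = {GAUSSIAN}

_TOF_OSEM_CONSTANTS = dict(
    acquisition_time=3.0,
    matrix_size=256,
    z_filter="None",
    gaussian_fwhm=5.0,
    iterations=2,
    subsets=28,
    algorithm="TOF-OSEM",
)

_UPDATE_ITERS = (1, 2, 3, 4, 5, 6, 8, 10)
_UPDATE_SUBSETS = (16, 28, 32)


def _default_groups() -> dict[str, InvestigationGroup]:
    groups: dict[str, InvestigationGroup] = {}

    def add(name, varied, levels, constants, aggregate_over=None):
        groups[name] = InvestigationGroup(
            name=name,
            varied_parameter=varied,
            levels=tuple(levels),
            constants=constants,
            aggregate_over=aggregate_over,
        )

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("acquisition_time")
    add(ACQ_TIME, "acquisition_time",
        (1, 1.5, 2, 3, 4, 5, 6, 8, 10, 12.5, 15), c)

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("matrix_size")
    add(MATRIX, "matrix_size", (128, 192, 256, 384), c)

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("z_filter")
    add(ZFILTER, "z_filter", ("None", "Light", "Standard", "Heavy"), c)

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("gaussian_fwhm")
    add(GAUSSIAN, "gaussian_fwhm",
        tuple(x / 2 for x in range(0, 21)), c)  # 0, 0.5, ..., 10 mm

    add(BPL_BETA, "beta",
        (50, 100, 150, 200, 250, 300, 350, 400, 500, 600, 700, 800, 1000),
        dict(acquisition_time=3.0, matrix_size=256, z_filter="None",
             gaussian_fwhm=0.0, iterations=2, subsets=28,
             algorithm="TOF-BPL"))

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("iterations")
    c.pop("subsets")
    add(OSEM_UPDATES, "updates",
        tuple((i, s) for i in _UPDATE_ITERS for s in _UPDATE_SUBSETS), c)

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("iterations")
    c["subsets"] = None  # averaged over the 3 subset schemes per iteration
    add(OSEM_ITERATIONS, "iterations", _UPDATE_ITERS, c,
        aggregate_over="subsets")

    c = dict(_TOF_OSEM_CONSTANTS)
    c.pop("subsets")
    c["iterations"] = None  # averaged over the 8 iteration schemes per subset
    add(OSEM_SUBSETS, "subsets", _UPDATE_SUBSETS, c,
        aggregate_over="iterations")

    add(ALGORITHM, "algorithm", ALGORITHMS,
        dict(acquisition_time=3.0, matrix_size=256, z_filter="None",
             gaussian_fwhm=0.0, iterations=2, subsets=28, beta=350.0))

    return groups


DEFAULT_GROUPS = _default_groups()


def build_grid(
    config: Sequence[str] | None = None,
) -> list[tuple[InvestigationGroup, list[SettingSpec]]]:
    """Enumerate every setting variation of the requested groups.

    Parameters
    ----------
    config
        Group names to include; ``None`` selects all nine default groups.
        An explicitly empty sequence yields an empty grid.

    Returns
    -------
    list of (InvestigationGroup, list of SettingSpec)
        One fully specified SettingSpec per level of each group (94 in
        total over the nine default groups).
    """
    names = DEFAULT_GROUP_NAMES if config is None else tuple(config)
    out = []
    for raw in names:
        key = _norm(raw)
        if key not in DEFAULT_GROUPS:
            raise GridValidationError(
                f"unknown investigation group {raw!r}; known: "
                f"{list(DEFAULT_GROUP_NAMES)}"
            )
        group = DEFAULT_GROUPS[key]
        specs = []
        for level in group.levels:
            kwargs = dict(group.constants)
            if group.varied_parameter == "updates":
                kwargs["iterations"], kwargs["subsets"] = level
            else:
                kwargs[group.varied_parameter] = level
            specs.append(SettingSpec(**kwargs))
        out.append((group, specs))
    return out


def level_x_value(group: InvestigationGroup, level) -> float:
    """Raw numeric x-value of a level prior to :func:`rescale_x`."""
    if group.varied_parameter == "z_filter":
        return encode_zfilter(level)
    if group.varied_parameter == "updates":
        i, s = level
        return float(i * s)
    if group.varied_parameter == "algorithm":
        raise GridValidationError(
            "algorithm levels are categorical and carry no numeric x-value"
        )
    return float(level)


def rescale_x(group_name: str, x_values) -> "pd.Series | list[float] | float":
    """Rescale numeric x-values of a group for model fitting/correction.

    Acquisition time, encoded z-filter weight and OSEM iterations are
    multiplied by 10; the Gaussian filter width is shifted by +2 (so the
    0 mm level survives 1/x and log(x) forms); every other group is passed
    through unchanged.  Transformed values must be positive and never 1
    (log(1)=0 would break the 1/log form); a violation raises rather than
    silently dropping the level.
    """
    key = _norm(group_name)
    if key not in DEFAULT_GROUPS:
        raise GridValidationError(f"unknown investigation group {group_name!r}")
    scalar = False
    try:
        xs = [float(v) for v in x_values]
    except TypeError:
        xs = [float(x_values)]
        scalar = True
    if key in _RESCALE_X10:
        out = [10.0 * v for v in xs]
    elif key in _RESCALE_SHIFT2:
        out = [v + 2.0 for v in xs]
    else:
        out = list(xs)
    bad = [v for v in out if v <= 0 or v == 1.0]
    if bad:
        raise GridValidationError(
            f"group {group_name!r}: transformed x-values {bad} are not "
            "admissible for reciprocal/logarithmic model forms"
        )
    return out[0] if scalar else out


def grid_to_frame(grid=None) -> pd.DataFrame:
    """Serialize a grid (default: all 9 groups) to a tidy DataFrame."""
    if grid is None:
        grid = build_grid()
    rows = []
    for group, specs in grid:
        for level, spec in zip(group.levels, specs):
            row = asdict(spec)
            row["group"] = group.name
            row["level"] = str(level)
            if group.varied_parameter != "algorithm":
                row["x_value"] = level_x_value(group, level)
            else:
                row["x_value"] = float("nan")
            rows.append(row)
    cols = ["group", "level", "x_value"] + [
        f.name for f in SettingSpec.__dataclass_fields__.values()
    ]
    return pd.DataFrame(rows)[cols]


def grid_to_csv(path_or_buf, grid=None) -> None:
    grid_to_frame(grid).to_csv(path_or_buf, index=False)
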