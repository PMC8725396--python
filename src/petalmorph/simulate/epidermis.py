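"""Synthetic petal-epidermis sheets with prescribed cell-shape gradients.

Each (species, stage) combination carries three quadratic curves in the
standardized midrib position p (PAMR in [0, 1]):

    CL*(p)     = c0 + c1 p + c2 p^2      target cell lobeyness, clamped to [0, 0.6]
    log CA*(p) = a0 + a1 p + a2 p^2      target log cell area (um^2)
    CLWR*(p)   = w0 + w1 p + w2 p^2      target length-to-width ratio

Cells are lobed star polygons r(theta) = R (1 + a sin(k theta)) stretched
along the longitudinal (y) axis to the target CLWR and scaled to the target
area.  Because solidity is invariant under affine maps, the lobe amplitude
``a`` alone controls lobeyness; it is calibrated against a precomputed
amplitude-to-lobeyness table for the chosen lobe count.  Per-cell targets
receive truncated log-normal multiplicative noise (truncation at three
standard deviations keeps targets positive and within the achievable
lobeyness range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from petalmorph.geometry import CellRecord, Polygon, GeometryError

__all__ = [
    "ScenarioSpec",
    "EpidermisData",
    "gen_epidermis",
    "scenario_preset",
    "max_achievable_cl",
]

_AMPLITUDE_MAX = 0.99  # r(theta) must stay positive; a < 1

Curve = tuple[float, float, float]


@dataclass
class ScenarioSpec:
    """Study design for one synthetic epidermis experiment.

    ``curves`` maps (species, stage) to the three coefficient triples
    ``{"cl": (c0, c1, c2), "log_ca": (a0, a1, a2), "clwr": (w0, w1, w2)}``.
    """

    name: str
    curves: dict[tuple[str, str], dict[str, Curve]]
    n_individuals: int = 3
    n_images: int = 9
    cells_per_image: int = 40
    noise_sd: float = 0.12
    lobe_count: int = 6
    n_vertices: int = 72
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError("n_images must be >= 2")
        if self.cells_per_image < 1:
            raise ValueError("cells_per_image must be >= 1")
        if self.lobe_count < 2:
            raise ValueError("lobe_count must be >= 2")
        if self.n_vertices < 6 * self.lobe_count:
            raise ValueError("too few vertices to resolve the lobes")
        for key, cur in self.curves.items():
            for which in ("cl", "log_ca", "clwr"):
                if which not in cur or len(cur[which]) != 3:
                    raise ValueError(f"curves[{key}] needs a 3-coefficient {which!r} entry")
            p = np.linspace(0, 1, 101)
            if np.any(self._eval(cur["clwr"], p) <= 0):
                raise ValueError(f"curves[{key}]: CLWR*(p) must stay positive")

    @staticmethod
    def _eval(coeffs: Curve, p: np.ndarray) -> np.ndarray:
        c0, c1, c2 = coeffs
        return c0 + c1 * p + c2 * p**2

    def target_cl(self, key: tuple[str, str], p: np.ndarray) -> np.ndarray:
        return np.clip(self._eval(self.curves[key]["cl"], p), 0.0, 0.6)

    def target_log_ca(self, key: tuple[str, str], p: np.ndarray) -> np.ndarray:
        return self._eval(self.curves[key]["log_ca"], p)

    def target_clwr(self, key: tuple[str, str], p: np.ndarray) -> np.ndarray:
        return self._eval(self.curves[key]["clwr"], p)

    @property
    def species(self) -> list[str]:
        return sorted({sp for sp, _ in self.curves})

    @property
    def stages(self) -> list[str]:
        return sorted({st for _, st in self.curves})


@dataclass
class EpidermisData:
    """Generated sheet: per-cell records, outlines and the planted truth."""

    records: list[CellRecord]
    polygons: dict[str, Polygon]
    truth: dict = field(default_factory=dict)

    def cell_table(self) -> pd.DataFrame:
        rows = [
            {
                "species": r.species, "stage": r.stage, "individual": r.individual,
                "image_index": r.image_index, "pamr": r.pamr, "cell_id": r.cell_id,
                "cl": r.cl, "ca_um2": r.ca, "clwr": r.clwr,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def polygon_arrays(self) -> dict[str, np.ndarray]:
        return {cid: poly.vertices for cid, poly in self.polygons.items()}


@lru_cache(maxsize=8)
def _amplitude_table(k: int, n_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """Monotone table (amplitude grid, lobeyness) for the k-lobed star."""
    from scipy.spatial import ConvexHull

    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    amps = np.linspace(0.0, _AMPLITUDE_MAX, 400)
    cls = np.empty_like(amps)
    for i, a in enumerate(amps):
        r = 1.0 + a * np.sin(k * theta)
        v = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * abs(x @ np.roll(y, -1) - y @ np.roll(x, -1))
        cls[i] = 1.0 - area / ConvexHull(v).volume
    cls = np.maximum.accumulate(cls)  # enforce monotonicity against round-off
    return amps, cls


def max_achievable_cl(k: int = 6, n_vertices: int = 72) -> float:
    """Largest lobeyness a k-lobed star with positive radius can reach."""
    return float(_amplitude_table(k, n_vertices)[1][-1])


def _star_vertices(a: float, k: int, n_vertices: int) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = 1.0 + a * np.sin(k * theta)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(x @ np.roll(y, -1) - y @ np.roll(x, -1))


def make_cell_polygon(
    cl: float, ca: float, clwr: float, k: int = 6, n_vertices: int = 72,
    center: tuple[float, float] = (0.0, 0.0),
) -> Polygon:
    """Build one cell outline hitting the three shape targets.

    Lobe amplitude is read off the calibration table (solidity is
    affine-invariant, so the later stretch and scaling do not disturb it);
    the y-stretch sets CLWR and a final uniform scaling sets the area.
    """
    amps, cls = _amplitude_table(k, n_vertices)
    if cl < 0 or cl > cls[-1] + 1e-12:
        raise GeometryError(
            f"target lobeyness {cl:.3f} unreachable for k={k} "
            f"(max achievable {cls[-1]:.3f})"
        )
    a = float(np.interp(cl, cls, amps))
    v = _star_vertices(a, k, n_vertices)
    ext = v.max(axis=0) - v.min(axis=0)
    v[:, 1] *= clwr * ext[0] / ext[1]  # longitudinal axis is y
    v *= np.sqrt(ca / _shoelace(v))
    v += np.asarray(center)
    return Polygon(v, longitudinal_axis="y")


def gen_epidermis(spec: ScenarioSpec) -> EpidermisData:
    """Generate the full synthetic sheet for a scenario.

    One petal per (species, stage, individual); ``n_images`` equally spaced
    midrib positions per petal; ``cells_per_image`` cells per image.  The
    recorded per-cell metrics are *measured* from the generated outlines,
    exactly as the measurement stage would produce them.  Deterministic
    under a fixed seed.
    """
    from petalmorph.geometry import lobeyness, polygon_area, clwr as measure_clwr

    rng = np.random.default_rng(spec.seed)
    records: list[CellRecord] = []
    polygons: dict[str, Polygon] = {}
    targets: dict[str, dict[str, float]] = {}

    p_grid = np.linspace(0.0, 1.0, spec.n_images)
    max_cl = max_achievable_cl(spec.lobe_count, spec.n_vertices)

    for (species, stage) in sorted(spec.curves):
        for ind in range(1, spec.n_individuals + 1):
            individual = f"{species}_{ind}"
            for img_idx, p in enumerate(p_grid, start=1):
                cl_t = float(spec.target_cl((species, stage), np.array([p]))[0])
                log_ca_t = float(spec.target_log_ca((species, stage), np.array([p]))[0])
                clwr_t = float(spec.target_clwr((species, stage), np.array([p]))[0])
                # truncated log-normal multiplicative noise on each target
                z = np.clip(
                    rng.normal(0.0, spec.noise_sd, size=(spec.cells_per_image, 3)),
                    -3 * spec.noise_sd, 3 * spec.noise_sd,
                )
                cl_cell = np.clip(cl_t * np.exp(z[:, 0]), 0.0, 0.6)
                ca_cell = np.exp(log_ca_t) * np.exp(z[:, 1])
                clwr_cell = clwr_t * np.exp(z[:, 2])
                for j in range(spec.cells_per_image):
                    cid = f"{species}_{stage}_{ind}_img{img_idx}_c{j + 1}"
                    if cl_cell[j] > max_cl:
                        raise GeometryError(
                            f"unreachable target lobeyness {cl_cell[j]:.3f} at "
                            f"{species}/{stage} image {img_idx} (p={p:.2f}); "
                            f"max for k={spec.lobe_count} is {max_cl:.3f}"
                        )
                    spacing = 3.0 * np.sqrt(ca_cell[j])
                    center = (j * spacing, img_idx * 10 * spacing)
                    poly = make_cell_polygon(
                        cl_cell[j], ca_cell[j], clwr_cell[j],
                        k=spec.lobe_count, n_vertices=spec.n_vertices, center=center,
                    )
                    _, cl_meas = lobeyness(poly)
                    records.append(CellRecord(
                        species=species, stage=stage, individual=individual,
                        image_index=img_idx, pamr=float(p), cell_id=cid,
                        cl=cl_meas, ca=polygon_area(poly), clwr=measure_clwr(poly),
                    ))
                    polygons[cid] = poly
                    targets[cid] = {
                        "cl": float(cl_cell[j]), "ca": float(ca_cell[j]),
                        "clwr": float(clwr_cell[j]),
                    }

    truth = {
        "scenario": spec.name,
        "curves": {f"{sp}|{st}": cur for (sp, st), cur in spec.curves.items()},
        "cell_targets": targets,
        "seed": spec.seed,
    }
    return EpidermisData(records=records, polygons=polygons, truth=truth)


# ---------------------------------------------------------------------------
# Presets: the two study scenarios.

_BASAL_CL: Curve = (0.02, 0.50, -0.22)       # lobeyness rises toward the apex
_FLAT_CL: Curve = (0.02, 0.0, 0.0)           # juvenile: regular walls throughout
_BUD_LOGCA: Curve = (6.9, -0.5, -0.7)        # area shrinks toward the apex
_MATURE_LOGCA: Curve = (7.4, -0.5, -0.7)
_DERIVED_BUD_LOGCA: Curve = (6.8, 0.3, 0.0)  # moderate apical increase
_DERIVED_MATURE_LOGCA: Curve = (7.5, 0.5, -0.4)
_BASAL_CLWR: Curve = (2.2, -1.5, 0.5)        # elongated cells at the petal base
_FLAT_CLWR: Curve = (1.5, -0.4, 0.1)


def scenario_preset(name: str, *, seed: int | None = None, **overrides) -> ScenarioSpec:
    """Named study scenarios.

    ``pedomorphic``: the basal species shows the apical lobeyness gradient
    already in buds; the derived species is flat in buds and only acquires
    the gradient at maturity (delayed differentiation).  ``non_pedomorphic``:
    both species share the basal species' curves at both stages.
    Species labels: ``A`` = basal (ancestral-type), ``B`` = derived.
    """
    if name == "pedomorphic":
        curves = {
            ("A", "bud"): {"cl": _BASAL_CL, "log_ca": _BUD_LOGCA, "clwr": _BASAL_CLWR},
            ("A", "mature"): {"cl": _BASAL_CL, "log_ca": _MATURE_LOGCA, "clwr": _BASAL_CLWR},
            ("B", "bud"): {"cl": _FLAT_CL, "log_ca": _DERIVED_BUD_LOGCA, "clwr": _FLAT_CLWR},
            ("B", "mature"): {"cl": _BASAL_CL, "log_ca": _DERIVED_MATURE_LOGCA, "clwr": _FLAT_CLWR},
        }
    elif name == "non_pedomorphic":
        curves = {
            ("A", "bud"): {"cl": _BASAL_CL, "log_ca": _BUD_LOGCA, "clwr": _BASAL_CLWR},
            ("A", "mature"): {"cl": _BASAL_CL, "log_ca": _MATURE_LOGCA, "clwr": _BASAL_CLWR},
            ("B", "bud"): {"cl": _BASAL_CL, "log_ca": _BUD_LOGCA, "clwr": _BASAL_CLWR},
            ("B", "mature"): {"cl": _BASAL_CL, "log_ca": _MATURE_LOGCA, "clwr": _BASAL_CLWR},
        }
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    return ScenarioSpec(name=name, curves=curves, seed=seed, **overrides)
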