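"""Synthetic binary images of known fractal dimension.

Two families:

* Deterministic rasterizations of classical curves (Koch snowflake,
  Sierpinski gasket, Cesàro curve, plus line / filled-square / circle
  calibration shapes) whose box-counting dimensions are known in closed
  form — validation fixtures for the estimator.

* Seeded two-class "pseudo-histology" populations: textured edge maps
  whose measured box-counting dimension is steered to a per-class target
  distribution.  These stand in for real slide edge maps downstream; only
  the dimension distribution matters to the classifier, so no attempt is
  made to imitate tissue appearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.draw import circle_perimeter, line

from .boxcount import DEFAULT_EPSILONS, box_count_series, fit_dimension

FRACTAL_KINDS = (
    "koch_snowflake",
    "sierpinski",
    "cesaro",
    "line",
    "filled_square",
    "disk_boundary",
)

BENIGN_SUBTYPES = ("A", "F", "PT", "TA")
MALIGNANT_SUBTYPES = ("DC", "LC", "MC", "PC")


@dataclass
class FractalSpec:
    """Recipe for one deterministic fractal raster.

    ``step_px`` applies to the motif-substitution curves (Koch snowflake,
    Cesàro): the curve is drawn so its finest motif segment spans that many
    pixels.  A 1-px stroke cannot represent sub-pixel motif structure, and
    steps much above 2 px leave resolvable straight runs that dilute the
    scaling signal; 1.5 px minimizes the discretization bias of the
    box-count estimate on curves of known dimension.
    """

    kind: str
    iterations: int = 5
    size: int = 1024
    angle: float = 60.0  # cesaro only, degrees in (0, 90)
    step_px: float = 1.5  # finest motif segment, motif curves only

    def __post_init__(self) -> None:
        if self.kind not in FRACTAL_KINDS:
            raise ValueError(f"unknown fractal kind {self.kind!r}")
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.kind == "cesaro" and not 0.0 < self.angle < 90.0:
            raise ValueError("cesaro angle must lie in (0, 90) degrees")
        if self.step_px < 1.0:
            raise ValueError("step_px must be >= 1 pixel")


@dataclass
class PopulationSpec:
    """Recipe for a seeded two-class edge-map population.

    Per-image dimension targets are drawn from class-specific normals
    N(mean, sd); each image's texture density is then tuned until its
    measured dimension matches its target.  Benign slides carry the
    higher mean by default, matching the empirical direction for H&E
    stains (more extracellular structure, higher complexity).
    """

    n_per_class: int = 40
    fd_mean_benign: float = 1.80
    fd_mean_malignant: float = 1.55
    fd_sd: float = 0.05
    seed: int = 0
    size: int = 256
    epsilons: Sequence[int] = DEFAULT_EPSILONS

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.fd_sd <= 0:
            raise ValueError("fd_sd must be positive")
        for m in (self.fd_mean_benign, self.fd_mean_malignant):
            if not 1.0 < m < 2.0:
                raise ValueError("target means must lie in (1, 2)")
        if self.size < 64:
            raise ValueError("size must be >= 64")


# ---------------------------------------------------------------------------
# deterministic curves


def _koch_segment(p0: complex, p1: complex, iterations: int) -> list[complex]:
    """Vertices of the Koch curve from p0 to p1 (p1 excluded)."""
    if iterations == 0:
        return [p0]
    d = (p1 - p0) / 3.0
    a, b, c = p0 + d, p0 + d + d * complex(math.cos(-math.pi / 3), math.sin(-math.pi / 3)), p0 + 2 * d
    pts: list[complex] = []
    for q0, q1 in ((p0, a), (a, b), (b, c), (c, p1)):
        pts.extend(_koch_segment(q0, q1, iterations - 1))
    return pts


def _koch_snowflake_vertices(iterations: int) -> list[complex]:
    # equilateral triangle, oriented so the bumps point outward
    v = [complex(0, 0), complex(1, 0), complex(0.5, math.sqrt(3) / 2)]
    pts: list[complex] = []
    for q0, q1 in ((v[0], v[1]), (v[1], v[2]), (v[2], v[0])):
        pts.extend(_koch_segment(q0, q1, iterations))
    pts.append(v[0])  # close the outline
    return pts


def _cesaro_vertices(iterations: int, angle_deg: float) -> list[complex]:
    """Generalized Koch (Cesàro) curve across the unit interval.

    Each segment is replaced by four of length 1/(2(1+cos a)) with heading
    changes (+a, −2a, +a); a = 60° recovers the Koch curve.  The similarity
    dimension is log 4 / log(2(1+cos a)), increasing with a toward 2.
    """
    a = math.radians(angle_deg)
    r = 1.0 / (2.0 * (1.0 + math.cos(a)))
    rot_up = complex(math.cos(a), math.sin(a))
    rot_dn = complex(math.cos(a), -math.sin(a))

    def expand(p0: complex, p1: complex, depth: int) -> list[complex]:
        if depth == 0:
            return [p0]
        step = (p1 - p0) * r
        q1 = p0 + step
        q2 = q1 + step * rot_up
        q3 = q2 + step * rot_dn
        pts: list[complex] = []
        for s0, s1 in ((p0, q1), (q1, q2), (q2, q3), (q3, p1)):
            pts.extend(expand(s0, s1, depth - 1))
        return pts

    pts = expand(complex(0, 0), complex(1, 0), iterations)
    pts.append(complex(1, 0))
    return pts


def _sierpinski_outlines(iterations: int) -> list[tuple[complex, complex]]:
    """Edges of every depth-``iterations`` triangle of the gasket."""
    v = (complex(0, 0), complex(1, 0), complex(0.5, math.sqrt(3) / 2))

    def recurse(a: complex, b: complex, c: complex, depth: int, out: list):
        if depth == 0:
            out.extend([(a, b), (b, c), (c, a)])
            return
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        recurse(a, ab, ca, depth - 1, out)
        recurse(ab, b, bc, depth - 1, out)
        recurse(ca, bc, c, depth - 1, out)

    edges: list[tuple[complex, complex]] = []
    recurse(*v, iterations, edges)
    return edges


def _draw_polyline(canvas: np.ndarray, points: list[complex]) -> None:
    for p0, p1 in zip(points, points[1:]):
        rr, cc = line(
            int(round(p0.imag)), int(round(p0.real)),
            int(round(p1.imag)), int(round(p1.real)),
        )
        canvas[rr, cc] = 1


def _place(points: list[complex], size: int, scale: float, margin: int = 4) -> list[complex]:
    """Scale by ``scale`` px/unit and centre on a size×size canvas."""
    xs = [p.real for p in points]
    ys = [p.imag for p in points]
    span_x = (max(xs) - min(xs)) * scale
    span_y = (max(ys) - min(ys)) * scale
    if span_x > size - 1 - 2 * margin or span_y > size - 1 - 2 * margin:
        raise ValueError("resolution exhausted: iterations too deep for size")
    off_x = (size - 1 - span_x) / 2 - min(xs) * scale
    off_y = (size - 1 - span_y) / 2 - min(ys) * scale
    return [complex(p.real * scale + off_x, p.imag * scale + off_y) for p in points]


def render_fractal(spec: FractalSpec) -> np.ndarray:
    """Rasterize the named curve as a 1-px-stroke binary image.

    Pure and deterministic: repeated calls with the same spec are
    byte-identical.  Motif curves are drawn resolution-matched — the
    finest motif segment spans ``step_px`` pixels — so the raster carries
    scaling structure from the stroke scale up to the curve's extent;
    the Sierpinski gasket, an area recursion with structure at every
    scale, is drawn canvas-fit.  Raises ``resolution exhausted`` when the
    resolution-matched curve would overflow the canvas.
    """
    size = spec.size
    canvas = np.zeros((size, size), dtype=np.uint8)

    if spec.kind == "line":
        canvas[size // 2, :] = 1
        return canvas
    if spec.kind == "filled_square":
        canvas[:, :] = 1
        return canvas
    if spec.kind == "disk_boundary":
        r = size // 2 - 4
        rr, cc = circle_perimeter(size // 2, size // 2, r)
        canvas[rr, cc] = 1
        return canvas

    if spec.kind == "sierpinski":
        if (size - 9) / 2**spec.iterations < 1.0:
            raise ValueError("resolution exhausted: iterations too deep for size")
        edges = _sierpinski_outlines(spec.iterations)
        flat = _place([q for e in edges for q in e], size, scale=size - 9)
        for i in range(0, len(flat), 2):
            _draw_polyline(canvas, [flat[i], flat[i + 1]])
        return canvas

    if spec.kind == "koch_snowflake":
        points = _koch_snowflake_vertices(spec.iterations)
        ratio = 1.0 / 3.0
    elif spec.kind == "cesaro":
        points = _cesaro_vertices(spec.iterations, spec.angle)
        a = math.radians(spec.angle)
        ratio = 1.0 / (2.0 * (1.0 + math.cos(a)))
    else:  # pragma: no cover
        raise AssertionError(spec.kind)

    # px per unit so that the finest segment (ratio**iterations units) spans step_px
    scale = spec.step_px / ratio**spec.iterations
    _draw_polyline(canvas, _place(points, size, scale))
    return canvas


# ---------------------------------------------------------------------------
# pseudo-histology populations


def _measure_fd(image: np.ndarray, epsilons: Sequence[int]) -> float:
    return fit_dimension(box_count_series(image, epsilons)).dimension


def _segment_bank(rng: np.random.Generator, size: int, n_max: int) -> list[tuple]:
    """Pre-draw a fixed pool of short random strokes; an image built from
    the first n strokes is monotone in n, which makes density tuning a
    one-dimensional search."""
    segs = []
    for _ in range(n_max):
        r0 = rng.integers(0, size)
        c0 = rng.integers(0, size)
        length = rng.integers(8, 32)
        theta = rng.uniform(0, 2 * math.pi)
        r1 = int(np.clip(r0 + length * math.sin(theta), 0, size - 1))
        c1 = int(np.clip(c0 + length * math.cos(theta), 0, size - 1))
        segs.append((int(r0), int(c0), r1, c1))
    return segs


def _render_strokes(size: int, segs: list[tuple], n: int) -> np.ndarray:
    canvas = np.zeros((size, size), dtype=np.uint8)
    for r0, c0, r1, c1 in segs[:n]:
        rr, cc = line(r0, c0, r1, c1)
        canvas[rr, cc] = 1
    return canvas


def _tune_image(
    target: float,
    segs: list[tuple],
    size: int,
    epsilons: Sequence[int],
) -> np.ndarray:
    """Bisect the stroke count until the measured dimension hits the target."""
    lo, hi = 1, len(segs)
    fd_hi = _measure_fd(_render_strokes(size, segs, hi), epsilons)
    if fd_hi < target:
        raise ValueError(
            f"unattainable target dimension {target:.3f}: "
            f"maximum achievable on this canvas is {fd_hi:.3f}"
        )
    best_n, best_err = hi, abs(fd_hi - target)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        fd_mid = _measure_fd(_render_strokes(size, segs, mid), epsilons)
        err = abs(fd_mid - target)
        if err < best_err:
            best_n, best_err = mid, err
        if fd_mid < target:
            lo = mid
        else:
            hi = mid
    return _render_strokes(size, segs, best_n)


def generate_population(spec: PopulationSpec) -> list[tuple[np.ndarray, str, str]]:
    """Seeded two-class population of textured edge maps.

    Returns ``(image, label, subtype)`` triples; benign subtypes cycle
    over A/F/PT/TA and malignant over DC/LC/MC/PC.  Deterministic for a
    given spec (all randomness flows from one seeded generator).
    """
    rng = np.random.default_rng(spec.seed)
    n_max = max(8000, spec.size * 32)
    out: list[tuple[np.ndarray, str, str]] = []
    for label, mean, subtypes in (
        ("benign", spec.fd_mean_benign, BENIGN_SUBTYPES),
        ("malignant", spec.fd_mean_malignant, MALIGNANT_SUBTYPES),
    ):
        targets = rng.normal(mean, spec.fd_sd, size=spec.n_per_class)
        # keep sampled targets inside the range the canvas can realize
        targets = np.clip(targets, 1.05, 1.95)
        for i, target in enumerate(targets):
            segs = _segment_bank(rng, spec.size, n_max)
            img = _tune_image(float(target), segs, spec.size, spec.epsilons)
            out.append((img, label, subtypes[i % 4]))
    return out
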