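"""Synthetic visual scenes and object templates.

The simulator operates on binary bitmaps: a small set of object templates
(the Knowledge Network's stored objects) and square scenes in which one or
more templates are stamped at chosen positions.  Two glyphs are built in, a
"plus" (centred cross) and a "two" (digit-2), matching the classic
single-object / two-object stimuli used in selective-attention studies.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
stamping windows are half-open, so a template of size ``M`` placed at
``(r, c)`` covers rows ``r..r+M-1`` and columns ``c..c+M-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TemplateSet",
    "Stimulus",
    "make_template",
    "make_template_set",
    "compose_scene",
    "reference_scenes",
    "save_matrix",
    "load_matrix",
]

_GLYPHS = ("plus", "two")


def make_template(shape_name: str, size: int,
                  thickness: int | tuple[int, int] = 1) -> np.ndarray:
    """Return an ``size x size`` binary bitmap for a named glyph.

    ``plus`` is a centred cross: the middle row and middle column
    (2M-1 active cells at thickness 1).  ``two`` is a digit-2: full top,
    middle and bottom rows, a right descender between top and middle, and a
    left descender between middle and bottom (thickness applies only to the
    cross).

    Parameters
    ----------
    shape_name:
        One of ``"plus"`` or ``"two"``.
    size:
        Side length M of the bitmap, at least 3.
    thickness:
        Arm width of the cross: a single odd width for both bars, or a
        ``(horizontal, vertical)`` pair.  At ``(3, 1)`` the cross carries
        exactly as much ink (4M-3 cells) as the two.  Widths must leave at
        least one blank pixel on each side (``<= M - 2``).
    """
    if shape_name not in _GLYPHS:
        raise ValueError(
            f"unknown template shape {shape_name!r}; valid names: {', '.join(_GLYPHS)}"
        )
    if size < 3:
        raise ValueError(f"template size must be >= 3, got {size}")
    th, tv = thickness if isinstance(thickness, tuple) else (thickness, thickness)
    for t in (th, tv):
        if t < 1 or t % 2 == 0 or t > size - 2:
            raise ValueError(f"thickness must be odd and in [1, {size - 2}], got {t}")
    m = int(size)
    mid = m // 2
    w = np.zeros((m, m))
    if shape_name == "plus":
        w[mid - th // 2 : mid + th // 2 + 1, :] = 1.0
        w[:, mid - tv // 2 : mid + tv // 2 + 1] = 1.0
    else:  # two
        w[0, :] = 1.0
        w[mid, :] = 1.0
        w[m - 1, :] = 1.0
        w[1:mid, m - 1] = 1.0  # right descender, top bar -> middle bar
        w[mid + 1 : m - 1, 0] = 1.0  # left descender, middle bar -> bottom bar
    return w


@dataclass(frozen=True)
class TemplateSet:
    """K object templates of common size M.

    ``templates`` holds the binary bitmaps used to stamp scenes.  ``weights``
    is the view used as Knowledge-Network synaptic weights: each bitmap is
    scaled by ``(active pixel count) ** -alpha``, where ``normalize`` is the
    exponent alpha, or one of the named modes ``"none"`` (alpha = 0, raw
    bitmaps), ``"l2"`` (alpha = 1/2, unit Euclidean norm for binary
    bitmaps) and ``"sum"`` (alpha = 1, unit total weight).  The exponent
    balances two standing asymmetries between templates of unequal ink:
    at alpha = 1/2 every template has the same self-match (no feedback
    advantage), while larger alpha handicaps heavier templates' bottom-up
    match.  It is part of the calibrated reference configuration.
    """

    templates: tuple[np.ndarray, ...]
    labels: tuple[str, ...]
    normalize: str | float = "sum"
    weights: tuple[np.ndarray, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.templates) < 1 or len(self.templates) != len(self.labels):
            raise ValueError("need K >= 1 templates with one label each")
        m = self.templates[0].shape
        if any(t.shape != m or t.ndim != 2 or t.shape[0] != t.shape[1] for t in self.templates):
            raise ValueError("all templates must be square and share the same size M")
        for t, lab in zip(self.templates, self.labels):
            if not np.any(t):
                raise ValueError(f"template {lab!r} has no active cells")
            if t.min() < 0 or t.max() > 1:
                raise ValueError(f"template {lab!r} entries must lie in [0, 1]")
        named = {"none": 0.0, "l2": 0.5, "sum": 1.0}
        if isinstance(self.normalize, str):
            if self.normalize not in named:
                raise ValueError(f"unknown normalize mode {self.normalize!r}")
            alpha = named[self.normalize]
        else:
            alpha = float(self.normalize)
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"normalize exponent must lie in [0, 1], got {alpha}")
        ws = tuple(t / float(t.sum()) ** alpha for t in self.templates)
        object.__setattr__(self, "weights", ws)

    @property
    def size(self) -> int:
        """Template (and focus-of-attention) side length M."""
        return self.templates[0].shape[0]

    @property
    def n_templates(self) -> int:
        return len(self.templates)

    def weight_array(self) -> np.ndarray:
        """Weights stacked as a (K, M, M) array."""
        return np.stack(self.weights)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def make_template_set(size: int = 7, shapes: tuple[str, ...] = _GLYPHS,
                      normalize: str | float = "sum",
                      plus_thickness: int | tuple[int, int] = 3) -> TemplateSet:
    """Build a template set (plus and two) at side length ``size``.

    ``plus_thickness`` controls the cross's ink relative to the two: 3-pixel
    arms (33 cells at M=7) make the cross the heavier object, as the
    excitatory-matching study design needs for its cross bias, while
    ``(3, 1)`` gives both glyphs exactly equal ink (25 cells), the balanced
    geometry the prediction-error variant is calibrated at.
    """
    return TemplateSet(
        templates=tuple(
            make_template(s, size, thickness=plus_thickness if s == "plus" else 1)
            for s in shapes
        ),
        labels=tuple(shapes),
        normalize=normalize,
    )


@dataclass(frozen=True)
class Stimulus:
    """An N x N scene with a record of which template went where."""

    image: np.ndarray
    placements: tuple[tuple[str, int, int], ...]
    expected_winner: str | None = None

    @property
    def size(self) -> int:
        return self.image.shape[0]


def compose_scene(template_set: TemplateSet, placements, image_size: int,
                  expected_winner: str | None = None) -> Stimulus:
    """Stamp templates onto a zero background; overlaps combine by maximum.

    Each placement is ``(label, row, col)`` giving the top-left corner of the
    stamped template.  Overlap resolution by elementwise maximum keeps the
    image in [0, 1].
    """
    n = int(image_size)
    m = template_set.size
    if n < m:
        raise ValueError(f"image size N={n} must be >= template size M={m}")
    image = np.zeros((n, n))
    for placement in placements:
        label, row, col = placement
        if label not in template_set.labels:
            raise ValueError(f"placement {placement!r} names unknown template {label!r}")
        if not (0 <= row and 0 <= col and row + m <= n and col + m <= n):
            raise ValueError(
                f"placement {placement!r} does not fit: need 0 <= row, col and "
                f"row+{m} <= {n}, col+{m} <= {n}"
            )
        patch = template_set.templates[template_set.index(label)]
        region = image[row : row + m, col : col + m]
        np.maximum(region, patch, out=region)
    return Stimulus(
        image=image,
        placements=tuple((str(l), int(r), int(c)) for l, r, c in placements),
        expected_winner=expected_winner,
    )


def reference_scenes(template_set: TemplateSet | None = None,
                     image_size: int = 21) -> dict[str, Stimulus]:
    """The three study scenes: single plus, single two, and plus/two.

    Single objects are centred; the two-object scene places the plus on the
    left and the two on the right at the same height, disjointly.  The
    expected winner of the two-object scene is the plus (the model's
    top-down bias selects the cross).
    """
    ts = template_set if template_set is not None else make_template_set()
    m, n = ts.size, image_size
    mid = (n - m) // 2
    gap = max(1, (n - 2 * m) // 3)
    left, right = gap, n - m - gap
    return {
        "plus": compose_scene(ts, [("plus", mid, mid)], n, expected_winner="plus"),
        "two": compose_scene(ts, [("two", mid, mid)], n, expected_winner="two"),
        "plus_two": compose_scene(
            ts, [("plus", mid, left), ("two", mid, right)], n, expected_winner="plus"
        ),
    }


def save_matrix(path, matrix: np.ndarray) -> None:
    """Write a matrix as whitespace-separated rows of plain text."""
    np.savetxt(path, np.asarray(matrix), fmt="%.10g")


def load_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))
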