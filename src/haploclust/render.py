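"""Deterministic pictorial output: SNP grid, tree panel, annotation track.

The picture follows the field's haplotype-view convention: SNP positions
are rows (ascending coordinate, with the position and the reference
nucleotide printed on the left), samples are columns ordered by the
clustering tree drawn above them, and each cell is colored against the
reference.  Two encodings exist:

* ``three_color`` — white for identical-to-reference, black for
  different, gray for no data;
* ``multi_color`` — red/blue/green/yellow for A/G/C/T, gray for no
  data, and a fixed auxiliary palette for the ten ambiguity codes.

PNG output is byte-deterministic for identical inputs and options (the
same cannot be promised for JPEG, whose encoders vary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from PIL import Image, ImageDraw, ImageFont

from .core import DataError, GeneModel, HaploTree, SNPMatrix, TreeNode
from .io import annotate_position

__all__ = [
    "RenderOptions",
    "COLOR_RGB",
    "AMBIGUITY_PALETTE",
    "cell_color",
    "leaf_display_order",
    "image_dimensions",
    "render_pictorial",
]

#: Fixed auxiliary palette for the ten ambiguity codes (multi-color
#: mode); every entry is distinct from the four base colors and gray.
AMBIGUITY_PALETTE: dict[str, str] = {
    "R": "orange",
    "Y": "purple",
    "S": "cyan",
    "W": "magenta",
    "K": "brown",
    "M": "pink",
    "B": "olive",
    "D": "teal",
    "H": "navy",
    "V": "salmon",
}

_BASE_COLORS = {"A": "red", "G": "blue", "C": "green", "T": "yellow"}

COLOR_RGB: dict[str, tuple[int, int, int]] = {
    "white": (255, 255, 255),
    "black": (0, 0, 0),
    "gray": (128, 128, 128),
    "red": (255, 0, 0),
    "blue": (0, 0, 255),
    "green": (0, 160, 0),
    "yellow": (255, 215, 0),
    "orange": (255, 140, 0),
    "purple": (128, 0, 128),
    "cyan": (0, 200, 200),
    "magenta": (255, 0, 255),
    "brown": (139, 69, 19),
    "pink": (255, 105, 180),
    "olive": (128, 128, 0),
    "teal": (0, 128, 128),
    "navy": (0, 0, 128),
    "salmon": (250, 128, 114),
}

_MISSING = {"N", "-"}

# Fixed layout metrics (pixels); image dimensions are an exact affine
# function of (n_positions, n_samples, show_space, cell_size) given
# these constants.
LEFT_MARGIN = 110
ANNOTATION_WIDTH = 64
TREE_PANEL_HEIGHT = 80
NAME_PANEL_HEIGHT = 80
PAD = 4


@dataclass(frozen=True)
class RenderOptions:
    """Display choices for the pictorial output."""

    mode: str = "three_color"
    show_letters: bool = False
    show_space: bool = False
    include_annotation: bool = True
    cell_size: int = 12
    max_pixels: int = 50_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("three_color", "multi_color"):
            raise DataError(
                f"mode must be 'three_color' or 'multi_color', "
                f"got {self.mode!r}"
            )
        if self.cell_size < 1:
            raise DataError("cell_size must be >= 1 pixel")


def cell_color(symbol: str, ref: str, mode: str = "three_color") -> str:
    """Color name for one cell given the reference symbol and mode."""
    sym = str(symbol)
    if mode == "three_color":
        if sym in _MISSING:
            return "gray"
        return "white" if sym == str(ref) else "black"
    if mode == "multi_color":
        if sym in _MISSING:
            return "gray"
        if sym in _BASE_COLORS:
            return _BASE_COLORS[sym]
        return AMBIGUITY_PALETTE[sym]
    raise DataError(f"unknown color mode {mode!r}")


def leaf_display_order(t: HaploTree) -> list[str]:
    """Left-to-right sample order given by the (deterministic) tree."""
    return t.leaf_order()


def image_dimensions(
    n_positions: int,
    n_samples: int,
    opts: RenderOptions,
    with_annotation: bool = False,
) -> tuple[int, int]:
    """Exact pixel dimensions of the rendered image."""
    cell = opts.cell_size
    gap = cell if opts.show_space else 0
    width = (
        LEFT_MARGIN
        + n_samples * cell
        + max(0, n_samples - 1) * gap
        + (ANNOTATION_WIDTH if with_annotation else 0)
        + PAD
    )
    height = TREE_PANEL_HEIGHT + NAME_PANEL_HEIGHT + n_positions * cell + PAD
    return width, height


def _leaf_x_centers(
    t: HaploTree, x0: int, cell: int, gap: int
) -> dict[str, float]:
    order = t.leaf_order()
    return {
        name: x0 + i * (cell + gap) + cell / 2.0
        for i, name in enumerate(order)
    }


def _draw_tree(
    draw: ImageDraw.ImageDraw,
    t: HaploTree,
    leaf_x: dict[str, float],
    y_top: int,
    y_bottom: int,
) -> None:
    root_h = max(t.root.height, 0.0)
    scale = (y_bottom - y_top - 4) / root_h if root_h > 0 else 0.0
    line = COLOR_RGB["black"]

    def node_y(node: TreeNode) -> float:
        return y_bottom - node.height * scale

    def node_x(node: TreeNode) -> float:
        if node.is_leaf:
            return leaf_x[node.name]  # type: ignore[index]
        return sum(node_x(c) for c in node.children) / len(node.children)

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        y = node_y(node)
        xs = [node_x(c) for c in node.children]
        draw.line([(min(xs), y), (max(xs), y)], fill=line, width=1)
        for child, x in zip(node.children, xs):
            draw.line([(x, y), (x, node_y(child))], fill=line, width=1)
            walk(child)

    walk(t.root)


def _text_color(background: tuple[int, int, int]) -> tuple[int, int, int]:
    r, g, b = background
    luminance = 0.299 * r + 0.587 * g + 0.114 * b
    return (0, 0, 0) if luminance > 128 else (255, 255, 255)


def render_pictorial(
    m: SNPMatrix,
    t: HaploTree,
    models: Optional[Sequence[GeneModel]] = None,
    opts: RenderOptions = RenderOptions(),
    path: str | Path = "haplotypes.png",
) -> None:
    """Render the clustering pictorial to a PNG or JPEG file.

    Rows are SNP positions (labels and reference nucleotide always
    printed), columns follow :func:`leaf_display_order`, cells are
    colored by :func:`cell_color`; optional letters, inter-column
    spacing, and a right-hand annotation sidebar (gene/exon/strand).
    The tree is drawn above the columns.  Rendering is a pure function
    of its inputs: identical calls yield byte-identical PNG files.
    """
    ext = Path(path).suffix.lower()
    if ext not in (".png", ".jpg", ".jpeg"):
        raise DataError(
            f"unsupported image extension {ext!r}: use .png, .jpg or .jpeg"
        )
    order = leaf_display_order(t)
    if set(order) != set(m.samples):
        raise DataError("tree leaves do not match the matrix samples")
    with_annotation = bool(models) and opts.include_annotation
    width, height = image_dimensions(
        m.n_positions, m.n_samples, opts, with_annotation
    )
    if width * height > opts.max_pixels:
        raise DataError(
            f"refusing to render a {width}x{height} image "
            f"({width * height} px > cap {opts.max_pixels}); "
            "narrow the region, shrink the cell size, or raise max_pixels"
        )
    cell = opts.cell_size
    gap = cell if opts.show_space else 0
    font = ImageFont.load_default()
    img = Image.new("RGB", (width, height), COLOR_RGB["white"])
    draw = ImageDraw.Draw(img)

    leaf_x = _leaf_x_centers(t, LEFT_MARGIN, cell, gap)
    _draw_tree(draw, t, leaf_x, 2, TREE_PANEL_HEIGHT - 2)

    # Vertical sample names (characters stacked), truncated to fit.
    max_chars = NAME_PANEL_HEIGHT // 10
    for name in order:
        x = leaf_x[name]
        for k, ch in enumerate(name[:max_chars]):
            draw.text(
                (x - 3, TREE_PANEL_HEIGHT + k * 10),
                ch, fill=COLOR_RGB["black"], font=font,
            )

    grid_top = TREE_PANEL_HEIGHT + NAME_PANEL_HEIGHT
    col_x = {
        name: LEFT_MARGIN + i * (cell + gap) for i, name in enumerate(order)
    }
    col_of = {name: m.sample_index(name) for name in order}
    for row in range(m.n_positions):
        y = grid_top + row * cell
        pos = int(m.positions[row])
        ref_sym = m.calls[row, 0]
        draw.text((2, y), f"{pos} {ref_sym}", fill=COLOR_RGB["black"],
                  font=font)
        for name in order:
            sym = m.calls[row, col_of[name]]
            rgb = COLOR_RGB[cell_color(sym, ref_sym, opts.mode)]
            x = col_x[name]
            draw.rectangle([x, y, x + cell - 1, y + cell - 1], fill=rgb)
            if opts.show_letters:
                draw.text((x + 2, y), sym, fill=_text_color(rgb), font=font)
        if with_annotation:
            gene, exon, strand = annotate_position(pos, models or [])
            ax = width - ANNOTATION_WIDTH
            if gene:
                bar = COLOR_RGB["black"] if exon.startswith("exon") \
                    else (170, 170, 170)
                draw.rectangle([ax + 2, y, ax + 18, y + cell - 1], fill=bar)
                draw.text((ax + 22, y), f"{strand}{exon[4:] or ''}",
                          fill=COLOR_RGB["black"], font=font)

    if ext == ".png":
        img.save(path, format="PNG")
    else:
        img.save(path, format="JPEG", quality=95)
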