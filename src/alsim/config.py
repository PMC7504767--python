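"""Run configuration and the pipeline's fixed constants."""

from __future__ import annotations

from dataclasses import dataclass, asdict

#: heatmap raster dimensions (pixels)
IMAGE_WIDTH = 280
IMAGE_HEIGHT = 300
#: featurization grid (columns x rows); 280/56 = 300/60 = 5 px cells
GRID_WIDTH = 56
GRID_HEIGHT = 60
#: potency color-gradient anchors: green / yellow / red pKi
GRADIENT_ANCHORS = (3.72, 5.75, 8.75)
#: additive smoothing per category before probability normalization
EPSILON = 0.5
#: regularization range and grid size for the GP alpha selection
ALPHA_BOUNDS = (1e-7, 1e-1)
N_ALPHA_CANDIDATES = 10


@dataclass
class RunConfig:
    """All tunable pipeline settings with their defaults.

    The image must tile exactly into the grid: ``image_width`` divisible
    by ``grid_width`` and ``image_height`` by ``grid_height``.
    """

    image_width: int = IMAGE_WIDTH
    image_height: int = IMAGE_HEIGHT
    grid_width: int = GRID_WIDTH
    grid_height: int = GRID_HEIGHT
    gradient_anchors: tuple[float, float, float] = GRADIENT_ANCHORS
    epsilon: float = EPSILON
    log_base: str = "e"
    mds_seed: int = 0
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS
    alpha_candidates: int = N_ALPHA_CANDIDATES

    def __post_init__(self) -> None:
        if self.image_width % self.grid_width:
            raise ValueError(
                f"image width {self.image_width} not divisible by "
                f"grid width {self.grid_width}")
        if self.image_height % self.grid_height:
            raise ValueError(
                f"image height {self.image_height} not divisible by "
                f"grid height {self.grid_height}")
        lo, mid, hi = self.gradient_anchors
        if not (lo < mid < hi):
            raise ValueError(f"gradient anchors must increase: {self.gradient_anchors}")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"log_base must be 'e' or '2', got {self.log_base!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        a_lo, a_hi = self.alpha_bounds
        if not (0 < a_lo < a_hi):
            raise ValueError(f"invalid alpha bounds {self.alpha_bounds}")

    @property
    def cell_size(self) -> tuple[int, int]:
        """Pixels per cell, (height, width)."""
        return (self.image_height // self.grid_height,
                self.image_width // self.grid_width)

    def to_dict(self) -> dict:
        return asdict(self)
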