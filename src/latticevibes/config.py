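"""Workflow configuration with serializable, overridable defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class WorkflowConfig:
    """All tunable constants of the workflow in one place.

    Every default is overridable from YAML/JSON via :meth:`load`; the
    docstrings of the consuming functions describe each constant's role.
    """

    # file paths
    model_path: str = ""
    map_path: str = ""
    bragg_path: str = ""
    output_dir: str = "latticevibes_out"

    # elastic network construction
    contact_cutoff: float = 4.0       # hard inter-atomic contact cutoff (A)
    exclude_hydrogen: bool = True
    exclude_solvent: bool = True
    occupancy_weighting: bool = False

    # lattice dynamics
    supercell: tuple = (8, 8, 8)
    kT: float = 1.0                   # thermal scale (spring units kT/A^2)

    # diffuse simulation
    density_spacing: float = 0.5      # real-space grid spacing (A)
    mask_blur_b: float = 50.0         # soft-mask Gaussian blur B (A^2)
    oversample: int = 4               # transform padding factor
    interp_order: int = 5             # Fourier interpolation spline order

    # halo refinement
    halo_count: int = 400
    resolution_window: tuple = (2.0, 2.5)   # Bragg selection window (A)
    refine_stages: int = 4
    init_gamma: float = 1.0

    # delta-PDF deconvolution
    pdf_resolution: float = 1.6       # delta-PDF truncation (A)
    peak_radius: float = 4.0          # spherical peak mask (A)
    low_res_exclusion: float = 5.0    # exclude d-spacing above this (A)

    # map processing
    shell_width: float = 0.02         # resolution-bin width (1/A)
    target_subdivision: tuple = (1, 1, 1)

    # reproducibility
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self):
        d = dataclasses.asdict(self)
        for key in ("supercell", "resolution_window", "target_subdivision"):
            d[key] = list(d[key])
        return d

    def save(self, path):
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path):
        path = str(path)
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data):
        kwargs = {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in data.items():
            if key not in names:
                raise ValueError(f"unknown config key: {key!r}")
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)

    def config_hash(self):
        import hashlib
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
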