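"""Centralised pipeline configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .registration import ICPParams

#: CBCT segmentation windows of the source protocol (Hounsfield units),
#: carried as provenance metadata only — this pipeline starts from meshes.
SEGMENTATION_METADATA = {
    "hard_tissue_hu": "+646.19 (+/- 24.57) to +1000",
    "airways_hu": "-1000 to 299.39 (+/- 17.2)",
}

#: ICP settings used by the cohort pipeline: registration accuracy is needed
#: to ~0.1 mm, so the run-time profile (fewer samples, looser RMS-change
#: stop) is preferred over the high-precision defaults of
#: :class:`airwaymorph.registration.ICPParams`.
PIPELINE_ICP = ICPParams(max_iterations=30, tolerance=1e-3, sample_size=2000)


@dataclass
class PipelineConfig:
    manifest: str = ""
    output_dir: str = "airwaymorph_out"
    pixel_mm: float = 0.1
    icp: ICPParams = field(default_factory=lambda: PIPELINE_ICP)
    cutoffs: tuple = (30.0, 50.0, 100.0)
    subgroup_cut_mm: float = 5.0
    peak_window: float = 0.05
    use_posterior_wall: bool = True
    seed: int = 0
    metadata: dict = field(default_factory=lambda: dict(SEGMENTATION_METADATA))

    def __post_init__(self):
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive percentages")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self._as_dict(), fh, indent=1)

    def _as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        return d

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "icp" in d:
            d["icp"] = ICPParams(**d["icp"])
        if "cutoffs" in d:
            d["cutoffs"] = tuple(d["cutoffs"])
        return cls(**d)

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self._as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
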