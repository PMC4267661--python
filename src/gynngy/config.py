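"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic tandem-donor data generator.

    The defaults describe a small multi-tissue experiment: every AS site
    gets a per-tissue read depth, regulated sites follow a two-level step
    profile whose span is ``regulated_delta``, noise sites have a constant
    near-zero minor usage, and the decoy/violation rates inject the read
    artefacts that the junction filters must remove.
    """

    seed: int = 0
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (3, 5)
    n_tissues: int = 8
    reads_per_site_per_tissue: int | tuple[int, int] = 60
    fraction_gynngy_donors: float = 0.6
    fraction_as: float = 0.5
    fraction_regulated: float = 0.3
    regulated_delta: float = 0.4
    noise_ums_range: tuple[float, float] = (0.005, 0.05)
    fraction_strand_ambiguous_decoys: float = 0.0
    fraction_shift_ambiguous_decoys: float = 0.0
    read_length: int = 50
    anchor_violation_rate: float = 0.0
    strand_specific: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "fraction_gynngy_donors",
            "fraction_as",
            "fraction_regulated",
            "fraction_strand_ambiguous_decoys",
            "fraction_shift_ambiguous_decoys",
            "anchor_violation_rate",
        ):
            _check_proportion(name, getattr(self, name))
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_tissues < 2:
            raise ValueError(f"n_tissues must be >= 2, got {self.n_tissues}")
        if not (0.0 < self.regulated_delta <= 1.0):
            raise ValueError(
                f"regulated_delta must be in (0, 1], got {self.regulated_delta}"
            )
        lo, hi = self.exons_per_gene
        if not (2 <= lo <= hi):
            raise ValueError(f"exons_per_gene range invalid: {self.exons_per_gene}")
        nlo, nhi = self.noise_ums_range
        if not (0.0 < nlo <= nhi <= 0.1):
            raise ValueError(
                f"noise_ums_range must lie within (0, 0.1], got {self.noise_ums_range}"
            )
        if self.read_length < 14:
            raise ValueError(f"read_length too short: {self.read_length}")
        r = self.reads_per_site_per_tissue
        if isinstance(r, int):
            if r < 0:
                raise ValueError(f"reads_per_site_per_tissue must be >= 0, got {r}")
        else:
            rlo, rhi = r
            if not (0 <= rlo <= rhi):
                raise ValueError(f"reads_per_site_per_tissue range invalid: {r}")

    def draw_depth(self, rng) -> int:
        r = self.reads_per_site_per_tissue
        if isinstance(r, int):
            return r
        return int(rng.integers(r[0], r[1] + 1))


@dataclass
class PipelineConfig:
    """Thresholds and paths shared by the pipeline stages.

    Defaults mirror the analysis conventions: testable tissues need >= 10
    reads, regulation calls use FDR <= 0.01, regulation-strength bins are
    0.05 / 0.1 / 0.25 on delta-UMS, and the permutation test runs 1e5
    rounds.
    """

    genome: str = ""
    gene_models: str = ""
    alignments: list[str] = field(default_factory=list)
    junction_table: str = ""
    conservation_track: str = ""
    gene_attributes: str = ""
    output_dir: str = "results"
    min_support: int = 1
    min_reads_per_tissue: int = 10
    fdr_threshold: float = 0.01
    delta_bins: tuple[float, float, float] = (0.05, 0.1, 0.25)
    n_permutations: int = 100_000
    max_shift: int = 10
    window: int = 50
    n_subsets: int = 100
    seed: int = 0
    strand_specific: bool = False

    def validate(self) -> None:
        _check_proportion("fdr_threshold", self.fdr_threshold)
        if self.min_support < 0:
            raise ValueError(f"min_support must be >= 0, got {self.min_support}")
        if self.min_reads_per_tissue < 1:
            raise ValueError(
                f"min_reads_per_tissue must be >= 1, got {self.min_reads_per_tissue}"
            )
        if self.n_permutations < 1:
            raise ValueError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )
        lo, mid, hi = self.delta_bins
        if not (0 < lo < mid < hi <= 1):
            raise ValueError(f"delta_bins must increase within (0, 1]: {self.delta_bins}")
        if self.max_shift < 1:
            raise ValueError(f"max_shift must be >= 1, got {self.max_shift}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "delta_bins" in raw:
            raw["delta_bins"] = tuple(raw["delta_bins"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["delta_bins"] = list(self.delta_bins)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
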