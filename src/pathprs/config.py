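"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .data import CC_PHENOTYPES
from .errors import ParameterError

#: Discovery GWAS p-value grid at which scores are computed.  Four values
#: are the conventional genome-wide / suggestive / nominal cut-offs; the
#: grid is configurable and always sorted ascending.
DEFAULT_THRESHOLDS: tuple[float, ...] = (5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 0.05)


def _default_case_shift() -> dict[str, float]:
    # Cases sit ~0.5 control SD above controls on ventricular volume and
    # ~0.5 SD below on every callosal measure.
    shift = {"LV": 0.5}
    for cc in CC_PHENOTYPES:
        shift[cc] = -0.5
    return shift


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic multi-cohort generator.

    Defaults emulate a consortium-style case-control structure at desk
    scale: three cohorts, ~0.8 case:control ratio, pathway-concentrated
    genetic effects, and a +0.5/-0.5 control-SD diagnostic shift on
    ventricular/callosal volumes.
    """

    n_cohorts: int = 3
    n_cases_per_cohort: int = 200
    n_controls_per_cohort: int = 250
    n_snps: int = 2000
    n_genes: int = 60
    n_chromosomes: int = 2
    genome_length: int = 20_000_000  # bp per chromosome
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_target: float = 0.5
    case_shift_sd: dict[str, float] = field(default_factory=_default_case_shift)
    pathway_effect_fraction: float = 0.5
    target_pathway: str = "ephrin"
    total_effect_var: float = 1.0  # sum of squared true log-ORs (expectation)
    genetic_corr_with_risk: float = 0.6
    covariate_effect_scale: float = 1.0
    discovery_n: int = 50_000
    gaf_rho: float = 0.3
    panss_rho: float = -0.2
    iq_rho: float = 0.2
    ld_blocks: int | None = None
    ld_rho: float = 0.0
    ancestry_from_genotypes: bool = False
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        counts = {
            "n_cohorts": self.n_cohorts,
            "n_cases_per_cohort": self.n_cases_per_cohort,
            "n_controls_per_cohort": self.n_controls_per_cohort,
            "n_snps": self.n_snps,
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "genome_length": self.genome_length,
            "discovery_n": self.discovery_n,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range must lie within (0, 0.5], got {self.maf_range!r}")
        for name, frac in (
            ("h2_target", self.h2_target),
            ("pathway_effect_fraction", self.pathway_effect_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {frac!r}")
        if not -1.0 <= self.genetic_corr_with_risk <= 1.0:
            raise ParameterError("genetic_corr_with_risk must lie in [-1, 1]")
        for name, rho in (("gaf_rho", self.gaf_rho), ("panss_rho", self.panss_rho), ("iq_rho", self.iq_rho)):
            if not -1.0 < rho < 1.0:
                raise ParameterError(f"{name} must lie in (-1, 1), got {rho!r}")
        if self.total_effect_var < 0:
            raise ParameterError("total_effect_var must be non-negative")
        if self.covariate_effect_scale < 0:
            raise ParameterError("covariate_effect_scale must be non-negative")
        if self.ld_blocks is not None:
            if self.ld_blocks <= 0:
                raise ParameterError("ld_blocks must be positive when set")
            if not 0.0 <= self.ld_rho < 1.0:
                raise ParameterError("ld_rho must lie in [0, 1)")
        return self

    @property
    def n_per_cohort(self) -> int:
        return self.n_cases_per_cohort + self.n_controls_per_cohort

    @property
    def n_samples(self) -> int:
        return self.n_cohorts * self.n_per_cohort

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    When ``simulate`` is set the input paths are generated into the
    output directory; otherwise they must point to existing files.
    """

    out_dir: str = "pathprs_run"
    simulate: SimulationConfig | None = None
    genotypes: str | None = None
    sumstats: str | None = None
    genes: str | None = None
    pathways: str | None = None
    phenotypes: str | None = None
    window: int = 20_000
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    remove_sd: float = 6.0
    winsorize_sd: float = 4.0
    alpha: float = 0.05
    correction_mode: str = "declared"  # or "effective"
    n_perm: int = 199
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.correction_mode not in ("declared", "effective"):
            raise ParameterError(f"unknown correction mode {self.correction_mode!r}")
        if self.window < 0:
            raise ParameterError("window must be non-negative")
        thr = tuple(self.thresholds)
        if any(not 0.0 < t <= 1.0 for t in thr):
            raise ParameterError("thresholds must lie in (0, 1]")
        if list(thr) != sorted(thr):
            raise ParameterError("thresholds must be sorted ascending")
        if self.remove_sd < self.winsorize_sd:
            raise ParameterError("remove_sd must be >= winsorize_sd")
        if self.n_perm < 100:
            raise ParameterError("n_perm must be >= 100")
        if self.simulate is None:
            for name in ("genotypes", "sumstats", "genes", "pathways", "phenotypes"):
                path = getattr(self, name)
                if path is None:
                    raise ParameterError(f"either simulate or an input path for {name!r} is required")
                if not Path(path).exists():
                    raise ParameterError(f"{name} path does not exist: {path}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable short hash of the analysis configuration.

        The output directory is excluded: two runs of the same analysis
        into different locations are the same configuration.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
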