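"""Simulation configuration.

All parameters of the synthetic-embryo generator live in :class:`SimConfig`:
tissue geometry, per-gene expression domains, two-state (telegraph) promoter
kinetics, genotype contrast, protein accumulation, and the camera model used
to render images. Rate units are per minute; lengths are pixels; dorsoventral
(DV) position is normalized to [0, 1] across the strip.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a SimConfig value is non-finite or out of range."""


@dataclass
class SimConfig:
    """Parameters of the synthetic embryo.

    Defaults are illustrative: the telegraph rates give a wild-type
    stationary mean of ~89 mRNA per cell (2 alleles x ON-fraction 2/3 x
    k_tx/k_deg), in the 50-150 range typical of a strongly expressed
    developmental gene, and the knockout slows mRNA degradation by
    ``ko_deg_factor``.
    """

    # tissue geometry
    n_cols: int = 16
    n_rows: int = 8
    jitter: float = 0.25          # center displacement, fraction of cell pitch
    cell_pitch_px: int = 60

    # expression domains in normalized DV coordinate, half-open [lo, hi)
    domains: dict = field(
        default_factory=lambda: {"rho": (0.30, 0.65), "mir9a": (0.20, 0.65)}
    )

    # telegraph transcription kinetics (per minute)
    k_on: float = 1.0
    k_off: float = 0.5
    k_tx: float = 20.0
    k_deg_wt: float = 0.3
    ko_deg_factor: float = 1.5    # KO degrades mRNA this factor slower
    leak_frac: float = 0.02       # basal transcription outside the domain
    n_alleles: int = 2
    t_end: float = 60.0           # simulated minutes
    nascent_mean: float = 3.0     # extra nascent transcripts at an active TS

    # protein accumulation
    protein_onset_wt: float = 80.0
    protein_onset_ko: float = 35.0
    k_translate: float = 1.0
    k_pdeg: float = 0.1

    # imaging / camera model
    psf_sigma_px: float = 1.2
    spot_amp: float = 120.0
    ts_amp_scale: float = 1.0     # TS amplitude = spot_amp * ts_amp_scale * load
    membrane_amp: float = 160.0
    nuclei_amp: float = 160.0
    nucleus_radius_frac: float = 0.28   # nucleus disk radius / cell pitch
    noise_sd: float = 15.0
    background_mean: float = 100.0
    min_spot_sep_px: float | None = None  # enforce spot spacing (rejection)

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        rates = {
            "k_on": self.k_on, "k_off": self.k_off, "k_tx": self.k_tx,
            "k_deg_wt": self.k_deg_wt, "leak_frac": self.leak_frac,
            "k_translate": self.k_translate, "k_pdeg": self.k_pdeg,
            "protein_onset_wt": self.protein_onset_wt,
            "protein_onset_ko": self.protein_onset_ko,
            "spot_amp": self.spot_amp, "ts_amp_scale": self.ts_amp_scale,
            "noise_sd": self.noise_sd, "background_mean": self.background_mean,
            "nascent_mean": self.nascent_mean,
        }
        for name, v in rates.items():
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")
        if self.ko_deg_factor <= 0 or not math.isfinite(self.ko_deg_factor):
            raise ConfigError(f"ko_deg_factor must be > 0, got {self.ko_deg_factor!r}")
        if not (0 <= self.jitter < 0.5):
            raise ConfigError(f"jitter must be in [0, 0.5), got {self.jitter!r}")
        if self.n_alleles not in (2, 4):
            raise ConfigError(f"n_alleles must be 2 or 4, got {self.n_alleles!r}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigError("lattice must have at least one cell")
        if self.cell_pitch_px < 4:
            raise ConfigError("cell_pitch_px must be >= 4")
        if self.psf_sigma_px <= 0:
            raise ConfigError("psf_sigma_px must be > 0")
        if self.t_end <= 0:
            raise ConfigError(f"t_end must be > 0, got {self.t_end!r}")
        for gene, (lo, hi) in self.domains.items():
            if not (0 <= lo <= 1 and 0 <= hi <= 1 and lo <= hi):
                raise ConfigError(f"domain interval for {gene!r} must lie in [0,1]")
        if "rho" in self.domains and "mir9a" in self.domains:
            rlo, rhi = self.domains["rho"]
            mlo, mhi = self.domains["mir9a"]
            if not (mlo <= rlo and rhi <= mhi):
                raise ConfigError(
                    "rho domain must be a subset of the mir9a domain "
                    f"(rho={self.domains['rho']}, mir9a={self.domains['mir9a']})"
                )

    # -- derived quantities ---------------------------------------------
    def k_deg(self, genotype: str) -> float:
        genotype = genotype.upper()
        if genotype == "WT":
            return self.k_deg_wt
        if genotype == "KO":
            return self.k_deg_wt / self.ko_deg_factor
        raise ConfigError(f"genotype must be 'WT' or 'KO', got {genotype!r}")

    def protein_onset(self, genotype: str) -> float:
        genotype = genotype.upper()
        if genotype == "WT":
            return self.protein_onset_wt
        if genotype == "KO":
            return self.protein_onset_ko
        raise ConfigError(f"genotype must be 'WT' or 'KO', got {genotype!r}")

    def stationary_mean(self, genotype: str = "WT") -> float:
        """Closed-form telegraph stationary mean mRNA per cell."""
        kd = self.k_deg(genotype)
        if kd == 0 or self.k_on + self.k_off == 0:
            raise ConfigError("stationary mean undefined for zero rates")
        p_on = self.k_on / (self.k_on + self.k_off)
        return self.n_alleles * p_on * self.k_tx / kd

    def stationary_variance(self, genotype: str = "WT") -> float:
        """Closed-form telegraph stationary variance of mRNA per cell.

        Per allele: var = mean * (1 + k_tx*k_off / ((k_on+k_off)(k_on+k_off+k_deg)));
        alleles are independent so cell variance sums.
        """
        kd = self.k_deg(genotype)
        ks = self.k_on + self.k_off
        mean_allele = self.stationary_mean(genotype) / self.n_alleles
        fano = 1.0 + self.k_tx * self.k_off / (ks * (ks + kd))
        return self.n_alleles * mean_allele * fano

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["domains"] = {g: list(iv) for g, iv in self.domains.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "domains" in d:
            d["domains"] = {g: tuple(iv) for g, iv in d["domains"].items()}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG for a keyed stream.

    Streams are identified by (seed, key...) so that e.g. each cell's
    transcription draws are independent of how many other cells exist.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
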