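"""Run configuration: a YAML file declaring inputs, run metadata and the
search/ORF/observability settings, with defaults matching the reference
acquisition and search setup (10 ppm precursor, 0.1 Da fragment
tolerance, trypsin with 1 missed cleavage, carbamidomethyl-C fixed,
oxidation-M and deamidation-NQ variable, expect cutoff 0.05, ORF minimum
301 nt, acquisition window m/z 150-2000 at charges 2-4)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .digestion import ObservabilityWindow
from .matcher import MatchConfig
from .pipeline import RunMeta


class ConfigError(ValueError):
    pass


@dataclass
class RunInput:
    meta: RunMeta
    mgf: Path


@dataclass
class RunConfig:
    contigs: Path
    runs: list[RunInput]
    out_dir: Path
    matcher: MatchConfig = field(default_factory=MatchConfig)
    window: ObservabilityWindow = field(default_factory=ObservabilityWindow)
    min_orf_nt: int = 301
    longest_per_stop: bool = True
    min_peptides: int = 1
    seed: int = 0
    annotations: dict[str, Path] = field(default_factory=dict)

    def validate_paths(self) -> None:
        missing = []
        if not self.contigs.exists():
            missing.append(str(self.contigs))
        for run in self.runs:
            if not run.mgf.exists():
                missing.append(str(run.mgf))
        for _k, p in self.annotations.items():
            if not p.exists():
                missing.append(str(p))
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    def digest_hash(self) -> str:
        """Stable hash of all settings for the reproducibility header."""
        payload = {
            "contigs": str(self.contigs),
            "runs": [
                {"sample": r.meta.sample, "fraction": r.meta.fraction,
                 "replicate": r.meta.replicate, "mgf": str(r.mgf)}
                for r in self.runs
            ],
            "matcher": vars(self.matcher) | {},
            "window": {
                "min_len": self.window.min_len, "max_len": self.window.max_len,
                "mz_min": self.window.mz_min, "mz_max": self.window.mz_max,
                "charges": sorted(self.window.charges),
            },
            "min_orf_nt": self.min_orf_nt,
            "longest_per_stop": self.longest_per_stop,
            "min_peptides": self.min_peptides,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    try:
        contigs = resolve(raw["contigs"])
        runs = [
            RunInput(
                meta=RunMeta(
                    sample=str(r["sample"]),
                    fraction=str(r["fraction"]),
                    replicate=int(r["replicate"]),
                ),
                mgf=resolve(r["mgf"]),
            )
            for r in raw["runs"]
        ]
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from None

    matcher_raw = raw.get("matcher", {})
    window_raw = raw.get("window", {})
    matcher = MatchConfig(
        precursor_tol_ppm=float(matcher_raw.get("precursor_tol_ppm", 10.0)),
        fragment_tol_da=float(matcher_raw.get("fragment_tol_da", 0.1)),
        expect_cutoff=float(matcher_raw.get("expect_cutoff", 0.05)),
        max_missed=int(matcher_raw.get("max_missed", 1)),
        max_var_mods=int(matcher_raw.get("max_var_mods", 3)),
    )
    window = ObservabilityWindow(
        min_len=int(window_raw.get("min_len", 6)),
        max_len=int(window_raw.get("max_len", 40)),
        mz_min=float(window_raw.get("mz_min", 150.0)),
        mz_max=float(window_raw.get("mz_max", 2000.0)),
        charges=frozenset(window_raw.get("charges", (2, 3, 4))),
    )
    annotations = {
        k: resolve(v) for k, v in (raw.get("annotations") or {}).items()
    }
    for fr in (r.meta.fraction for r in runs):
        if fr not in ("BF", "SNT"):
            raise ConfigError(f"{path}: fraction must be BF or SNT, got {fr!r}")
    return RunConfig(
        contigs=contigs,
        runs=runs,
        out_dir=resolve(raw.get("out_dir", "results")),
        matcher=matcher,
        window=window,
        min_orf_nt=int(raw.get("min_orf_nt", 301)),
        longest_per_stop=bool(raw.get("longest_per_stop", True)),
        min_peptides=int(raw.get("min_peptides", 1)),
        seed=int(raw.get("seed", 0)),
        annotations=annotations,
    )
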