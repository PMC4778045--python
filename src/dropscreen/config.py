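"""YAML run configuration shared by the CLI subcommands.

One file with sections per stage::

    seed: 7
    library:
      scaffold_peptide: TSFAEYWNLLSP
      variable_positions: [3, 7, 10]
      codons: [NNK, NNK, NNK]
      high_affinity: {FWL: 3.2}        # residues -> Kd (nM)
    screen:
      lam: 0.1
      n_drops: 100000
      threshold: 1.3
      leakage_rate: 0.2
      fluorescence: {baseline: 1.0, increment: 1.0, cooperativity: 1.35,
                     noise_sd: 0.1, width_gate_outlier_rate: 0.01}
    amplification: {transcripts_per_template: 300, efficiency_sd: 1.0}
    reads: {read_length: 56, error_rate: 0.001, n_reads: {bright: 20000,
            dark: 20000, input: 100000}}
    analysis: {q_cutoff: 20, max_mismatches_per_anchor: 1, adapter: ""}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .library import DegenerateCodon, LibraryDesign
from .reads import AmplificationModel, ReadConfig
from .screen import FluorescenceModel

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass
class RunConfig:
    seed: int
    design: LibraryDesign
    high_affinity: dict[str, float | None]
    lam: float
    n_drops: int
    threshold: float
    leakage_rate: float
    fluorescence: FluorescenceModel
    amplification: AmplificationModel
    read_config: ReadConfig
    n_reads: dict[str, int]
    q_cutoff: int = 20
    max_mismatches_per_anchor: int = 1
    adapter: str = ""


def default_config(seed: int = 0, n_drops: int = 100_000) -> RunConfig:
    """Demo configuration: 8000-member triad library with FWL as the one
    high-affinity binder, λ = 0.1."""
    return RunConfig(
        seed=seed,
        design=LibraryDesign(),
        high_affinity={"FWL": 3.2},
        lam=0.1,
        n_drops=n_drops,
        threshold=1.3,
        leakage_rate=0.2,
        fluorescence=FluorescenceModel(),
        amplification=AmplificationModel(),
        read_config=ReadConfig(),
        n_reads={"bright": 20_000, "dark": 20_000, "input": 100_000},
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; missing keys take demo defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    lib = raw.get("library", {})
    design_kwargs = {}
    if "scaffold_peptide" in lib:
        design_kwargs["scaffold_peptide"] = lib["scaffold_peptide"]
    if "variable_positions" in lib:
        design_kwargs["variable_positions"] = tuple(lib["variable_positions"])
    if "codons" in lib:
        design_kwargs["codon_scheme"] = tuple(
            DegenerateCodon(c) for c in lib["codons"]
        )
    if "scaffold_codons" in lib:
        design_kwargs["scaffold_codons"] = tuple(lib["scaffold_codons"])
    if "upstream" in lib:
        design_kwargs["upstream"] = lib["upstream"]
    if "downstream" in lib:
        design_kwargs["downstream"] = lib["downstream"]
    design = LibraryDesign(**design_kwargs)

    high = lib.get("high_affinity", {"FWL": 3.2})
    if isinstance(high, list):
        high = {r: None for r in high}

    screen = raw.get("screen", {})
    fl = FluorescenceModel(**screen.get("fluorescence", {}))
    amp = AmplificationModel(**raw.get("amplification", {}))

    reads = dict(raw.get("reads", {}))
    n_reads = reads.pop("n_reads", {"bright": 20_000, "dark": 20_000, "input": 100_000})
    read_config = ReadConfig(**reads)

    analysis = raw.get("analysis", {})
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        design=design,
        high_affinity=high,
        lam=float(screen.get("lam", 0.1)),
        n_drops=int(screen.get("n_drops", 100_000)),
        threshold=float(screen.get("threshold", 1.3)),
        leakage_rate=float(screen.get("leakage_rate", 0.2)),
        fluorescence=fl,
        amplification=amp,
        read_config=read_config,
        n_reads={k: int(v) for k, v in n_reads.items()},
        q_cutoff=int(analysis.get("q_cutoff", 20)),
        max_mismatches_per_anchor=int(analysis.get("max_mismatches_per_anchor", 1)),
        adapter=str(analysis.get("adapter", "")),
    )
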