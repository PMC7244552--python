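"""Synthetic quantitative-sequencing studies with known ground truth.

The generator walks the same physical path as a real experiment, so every
analysis stage has an oracle:

true per-gram taxon loads  ->  subject-level lognormal scatter
  ->  extraction (mass, lysate split, elution) with load-equation-consistent records
  ->  dPCR reading of the eluate (Poisson counting noise on aliquot copies)
  ->  library input copies + fixed reagent contaminant copies
  ->  replicate multinomial sequencing at a chosen depth
  ->  optional extraction blanks carrying only contaminants.

Contaminants are modelled as a fixed number of absolute template copies per
library preparation, independent of how much sample template is present.
That single assumption reproduces the field observation that contaminant
taxa surface only in low-input libraries: at 1e7 input copies a 40-copy
contaminant is a ~4e-6 relative share (invisible at typical depths), at
1e4 input copies it is ~0.4%.

All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchoring import AbsoluteAbundanceTable, ExtractionRecord
from .tables_io import TaxonCountTable

__all__ = [
    "CommunityConfig",
    "SimulatedStudy",
    "DEFAULT_CONTAMINANTS",
    "simulate_counts",
    "simulate_dpcr",
    "inject_contaminants",
    "simulate_study",
    "two_group_config",
    "replicate_config",
    "constant_taxon_scenario",
]

#: fixed reagent-borne template copies per library prep.  The taxa mirror
#: the usual kit-contaminant genera; 40 copies each is a calibration default
#: chosen so contaminants appear below ~1e4 input copies, not a measured value.
DEFAULT_CONTAMINANTS: dict[str, float] = {
    "Pseudomonas(g)": 40.0,
    "Acinetobacter(g)": 40.0,
    "Rhizobiales(f)": 40.0,
}


@dataclass(kw_only=True)
class CommunityConfig:
    """Everything needed to generate one synthetic study.

    ``group_loads`` holds the true per-taxon loads (16S copies per gram) for
    each group; ``biological_sigma_ln`` is the sd of the per-subject,
    per-taxon lognormal scatter in natural-log units (0 disables it).
    Extraction geometry defaults mirror a typical bead-beating protocol: 100 uL
    elution, half of a 400 uL lysate loaded, 50 mg of contents.
    ``library_input_copies`` is the total sample-template copy number
    entering library prep (contaminant shares scale against it).
    Setting ``dpcr_noise``/``sequencing_noise`` to False replaces the
    Poisson/multinomial draws with their expectations (rounded to integer
    reads), giving a noise-free identity pipeline for exact oracles.
    """

    taxa: tuple[str, ...]
    group_loads: Mapping[str, Sequence[float]]
    group_sizes: Mapping[str, int]
    seed: int
    depth: int = 28_000
    n_replicates: int = 1
    biological_sigma_ln: float = 0.35
    sample_mass_g: float = 0.05
    elution_ul: float = 100.0
    dead_ul: float = 400.0
    loaded_ul: float = 200.0
    dpcr_aliquot_ul: float = 2.0
    library_input_copies: float = 1.2e7
    contaminants: Mapping[str, float] = field(default_factory=dict)
    amplification_bias: Mapping[str, float] | None = None
    dilution_factors: tuple[float, ...] = (1.0,)
    n_blanks: int = 0
    dpcr_noise: bool = True
    sequencing_noise: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for group, loads in self.group_loads.items():
            arr = np.asarray(loads, dtype=float)
            if arr.shape != (len(self.taxa),):
                raise ValueError(f"group {group!r}: one load per taxon required")
            if np.any(arr < 0):
                raise ValueError(f"group {group!r}: loads must be >= 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 1 (0 allowed only for edge tests)")
        if set(self.group_sizes) != set(self.group_loads):
            raise ValueError("group_sizes and group_loads must cover the same groups")


@dataclass
class SimulatedStudy:
    """Ground truth plus everything the analysis modules consume."""

    config: CommunityConfig
    true_loads: AbsoluteAbundanceTable  # per sequencing sample, copies/g
    counts: TaxonCountTable  # all replicate libraries
    extraction_records: list[ExtractionRecord]
    blanks: TaxonCountTable | None
    metadata: pd.DataFrame

    def groups(self) -> dict[str, list[str]]:
        """Sample ids per group (sequencing samples, replicates included)."""
        out: dict[str, list[str]] = {}
        for sid, row in self.metadata.iterrows():
            if row["sample_type"] == "blank":
                continue
            out.setdefault(row["group"], []).append(sid)
        return out


def simulate_counts(
    true_composition: Sequence[float],
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Multinomial read counts for one library at the given depth."""
    comp = np.asarray(true_composition, dtype=float)
    if comp.size and not np.isclose(comp.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(int(depth), comp)


def simulate_dpcr(
    true_total_copies_in_aliquot: float,
    seed: int | np.random.Generator | None = None,
    aliquot_volume_ul: float = 1.0,
    noise: bool = True,
) -> float:
    """dPCR concentration reading with Poisson counting noise.

    The measured copy number in the aliquot is Poisson(true copies), so the
    relative error is ~``1/sqrt(copies)`` - about 10% at 100 copies.  The
    draw is rescaled to copies per uL of the aliquot volume.
    """
    lam = float(true_total_copies_in_aliquot)
    if lam < 0:
        raise ValueError("copies must be >= 0")
    if not noise:
        return lam / aliquot_volume_ul
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return float(rng.poisson(lam)) / aliquot_volume_ul


def inject_contaminants(
    sample_input_copies: Sequence[float],
    contaminant_copies: Sequence[float],
) -> np.ndarray:
    """Library composition after adding fixed contaminant template copies.

    Returns the relative composition over [sample taxa..., contaminant
    taxa...]; the contaminant share is ``c / (sample + c)`` and therefore
    grows as the sample input shrinks.
    """
    sample = np.asarray(sample_input_copies, dtype=float)
    contam = np.asarray(contaminant_copies, dtype=float)
    if np.any(sample < 0) or np.any(contam < 0):
        raise ValueError("copy numbers must be >= 0")
    combined = np.concatenate([sample, contam])
    total = combined.sum()
    if total == 0:
        raise ValueError("no template at all: empty library")
    return combined / total


def _noise_free_counts(composition: np.ndarray, depth: int) -> np.ndarray:
    """Deterministic expectation of a multinomial draw, rounded to reads."""
    return np.rint(composition * depth).astype(np.int64)


def simulate_study(config: CommunityConfig) -> SimulatedStudy:
    """Generate a full study from one config (reproducible by its seed)."""
    rng = np.random.default_rng(config.seed)
    taxa = list(config.taxa)
    contam_taxa = [t for t in config.contaminants if t not in taxa]
    contam_copies = np.array(
        [config.contaminants[t] for t in contam_taxa], dtype=float
    )
    all_taxa = taxa + contam_taxa
    bias = np.ones(len(taxa))
    if config.amplification_bias:
        for i, t in enumerate(taxa):
            bias[i] = config.amplification_bias.get(t, 1.0)

    count_rows: dict[str, np.ndarray] = {}
    truth_rows: dict[str, np.ndarray] = {}
    records: list[ExtractionRecord] = []
    meta_rows: list[dict] = []

    multi_dilution = len(config.dilution_factors) > 1
    for group, size in config.group_sizes.items():
        base = np.asarray(config.group_loads[group], dtype=float)
        for subject in range(1, size + 1):
            if config.biological_sigma_ln > 0:
                scatter = np.exp(
                    rng.normal(0.0, config.biological_sigma_ln, size=len(taxa))
                )
            else:
                scatter = 1.0
            subject_loads = base * scatter
            for dilution in config.dilution_factors:
                loads = subject_loads / dilution
                sid = f"{group}_m{subject}" + (
                    f"_d{dilution:g}" if multi_dilution else ""
                )
                total_load = loads.sum()
                # eluate concentration consistent with the load equation
                conc_true = (
                    total_load
                    * config.sample_mass_g
                    * config.loaded_ul
                    / (config.dead_ul * config.elution_ul)
                )
                aliquot_copies = conc_true * config.dpcr_aliquot_ul
                measured_conc = simulate_dpcr(
                    aliquot_copies,
                    seed=rng,
                    aliquot_volume_ul=config.dpcr_aliquot_ul,
                    noise=config.dpcr_noise,
                )
                records.append(
                    ExtractionRecord(
                        sample_id=sid,
                        dpcr_concentration=measured_conc,
                        elution_volume=config.elution_ul,
                        dead_volume=config.dead_ul,
                        extraction_volume=config.loaded_ul,
                        sample_mass=config.sample_mass_g,
                    )
                )
                # library: sample template scaled to the input copy number,
                # amplification bias applied, fixed contaminant copies added
                if total_load > 0:
                    template = loads * bias / (loads * bias).sum()
                    template = template * config.library_input_copies
                else:
                    template = np.zeros(len(taxa))
                composition = inject_contaminants(template, contam_copies)
                for rep in range(1, config.n_replicates + 1):
                    rep_id = sid if config.n_replicates == 1 else f"{sid}_r{rep}"
                    if config.sequencing_noise:
                        counts = simulate_counts(composition, config.depth, seed=rng)
                    else:
                        counts = _noise_free_counts(composition, config.depth)
                    count_rows[rep_id] = counts
                    truth_rows[rep_id] = np.concatenate(
                        [loads, np.zeros(len(contam_taxa))]
                    )
                    meta_rows.append(
                        {
                            "sample_id": rep_id,
                            "group": group,
                            "gi_site": "cecum",
                            "sample_type": "lumenal",
                            "subject_id": f"{group}_m{subject}",
                            "day": 10,
                        }
                    )

    blanks = None
    if config.n_blanks > 0:
        blank_rows = {}
        for b in range(1, config.n_blanks + 1):
            bid = f"blank_{b}"
            if contam_copies.sum() > 0:
                comp = np.concatenate(
                    [np.zeros(len(taxa)), contam_copies / contam_copies.sum()]
                )
                counts = (
                    simulate_counts(comp, config.depth, seed=rng)
                    if config.sequencing_noise
                    else _noise_free_counts(comp, config.depth)
                )
            else:
                counts = np.zeros(len(all_taxa), dtype=np.int64)
            blank_rows[bid] = counts
            meta_rows.append(
                {
                    "sample_id": bid,
                    "group": "",
                    "gi_site": "",
                    "sample_type": "blank",
                    "subject_id": "",
                    "day": 10,
                }
            )
        blanks = TaxonCountTable(
            pd.DataFrame.from_dict(blank_rows, orient="index", columns=all_taxa),
            validate=False,
        )

    counts_table = TaxonCountTable(
        pd.DataFrame.from_dict(count_rows, orient="index", columns=all_taxa),
        validate=False,
    )
    truth = AbsoluteAbundanceTable(
        pd.DataFrame.from_dict(truth_rows, orient="index", columns=all_taxa),
        validate=False,
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    return SimulatedStudy(
        config=config,
        true_loads=truth,
        counts=counts_table,
        extraction_records=records,
        blanks=blanks,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# study factories (the default desk-scale study conditions)
# ---------------------------------------------------------------------------

def _log_spaced_loads(
    n_taxa: int, low: float = 1e6, high: float = 1e10
) -> np.ndarray:
    """Per-taxon loads log-spaced over a realistic gut range (copies/g)."""
    return np.logspace(np.log10(high), np.log10(low), n_taxa)


def two_group_config(
    seed: int,
    n_taxa: int = 20,
    n_per_group: int = 6,
    depth: int = 28_000,
    fold_change: float = 8.0,
    changed_taxon: int | None = None,
    **overrides,
) -> CommunityConfig:
    """Diet-style two-group study with one truly shifted taxon.

    Twenty genus-level taxa with loads log-spaced over 1e6-1e10 copies/g
    (a typical cecal span), six mice per group, depth 28,000.  Group "A"
    carries ``fold_change`` times the base load of one mid-abundance taxon;
    every other taxon is a true null.
    """
    taxa = tuple(f"Taxon{i:02d}(g)" for i in range(1, n_taxa + 1))
    base = _log_spaced_loads(n_taxa)
    if changed_taxon is None:
        changed_taxon = n_taxa // 3  # mid-abundance, comfortably quantifiable
    loads_a = base.copy()
    loads_a[changed_taxon] *= fold_change
    return CommunityConfig(
        taxa=taxa,
        group_loads={"A": loads_a, "B": base},
        group_sizes={"A": n_per_group, "B": n_per_group},
        depth=depth,
        seed=seed,
        **overrides,
    )


def replicate_config(
    seed: int,
    n_taxa: int = 50,
    depth: int = 28_000,
    n_replicates: int = 4,
    abundance_span: float = 4.5,
    **overrides,
) -> CommunityConfig:
    """One specimen sequenced in technical replicates, for %CV curves.

    Fifty taxa with relative abundances log-spaced over ``abundance_span``
    decades reach from dominant members down past the detection limit at
    depth 28,000, populating the whole %CV-vs-abundance curve.
    """
    taxa = tuple(f"Taxon{i:02d}(g)" for i in range(1, n_taxa + 1))
    loads = 1e11 * np.logspace(0, -abundance_span, n_taxa)
    return CommunityConfig(
        taxa=taxa,
        group_loads={"replicate": loads},
        group_sizes={"replicate": 1},
        depth=depth,
        n_replicates=n_replicates,
        biological_sigma_ln=0.0,  # technical replicates share one extraction
        seed=seed,
        **overrides,
    )


def constant_taxon_scenario(
    seed: int,
    n_per_group: int = 6,
    depth: int = 28_000,
    **overrides,
) -> CommunityConfig:
    """Two-taxon scenario where relative and absolute analyses must disagree.

    Taxon A drops 10-fold between groups while taxon B's true load is
    unchanged, so the total load differs and B's *relative* abundance
    shifts even though nothing happened to it.  A relative-scale test
    flags both taxa; an absolute-scale test flags only A.
    """
    taxa = ("TaxonA(g)", "TaxonB(g)")
    loads_high = np.array([9e10, 1e10])
    loads_low = np.array([9e9, 1e10])
    return CommunityConfig(
        taxa=taxa,
        group_loads={"control": loads_high, "treated": loads_low},
        group_sizes={"control": n_per_group, "treated": n_per_group},
        depth=depth,
        biological_sigma_ln=overrides.pop("biological_sigma_ln", 0.2),
        seed=seed,
        **overrides,
    )
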