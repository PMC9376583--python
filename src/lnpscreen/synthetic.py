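"""Ground-truthed simulation of pooled barcode screens.

Generates everything a screen run produces — per-cell-type delivery
propensities, the sequenced input pool, and per-sample FASTQ reads — from an
explicit generative model, so the counting, quantification, and enrichment
stages can be validated against known truth:

* each LNP gets a log-normal relative delivery weight per cell type
  (delivery spans orders of magnitude across particles);
* the naked-barcode control gets a weight below the minimum LNP weight by a
  fixed factor (free DNA does not readily enter cells);
* molecules are sampled multinomially with probability proportional to
  input proportion x propensity; each molecule carries a fresh random 7-nt
  tag (UMI);
* PCR amplification bias is a per-molecule log-normal factor multiplying its
  read count; sequencing adds i.i.d. base substitutions;
* each read is the scaffold prefixed by one of the 8 staggered forward-primer
  tails, chosen uniformly (primers are mixed equimolar).

Indels, quality-dependent error profiles, and paired-end structure are not
modelled; reads are single-end over the full amplicon.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcodes import BASES, BarcodeScaffold, PrimerSet
from .library import Formulation, QCRecord, ScreenPool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimParams:
    """Noise model for a simulated screen.

    propensity_sdlog
        SD of log propensities (natural log). 1.0 spreads delivery over
        roughly two orders of magnitude across a 65-LNP pool.
    control_factor
        The naked control's weight as a fraction of the minimum LNP weight
        in each cell type (strictly below 1 keeps it the lowest by
        construction).
    pcr_bias_sd
        SD of the log-normal per-molecule amplification factor.
    error_rate
        Per-base substitution probability.
    reads_per_molecule
        Mean sequencing depth per sampled molecule; sets how many distinct
        molecules (UMIs) underlie a given read depth.
    """

    propensity_sdlog: float = 1.0
    control_factor: float = 0.1
    pcr_bias_sd: float = 0.5
    error_rate: float = 0.005
    reads_per_molecule: float = 10.0
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if self.propensity_sdlog < 0 or self.pcr_bias_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 < self.control_factor < 1:
            raise ValueError("control_factor must be in (0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.reads_per_molecule < 1:
            raise ValueError("reads_per_molecule must be >= 1")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    mouse: str
    cell_type: str
    tissue: str = ""
    depth: int = 10_000


@dataclass(frozen=True)
class GroundTruth:
    """True delivery weights behind a simulated screen."""

    propensity: pd.DataFrame          # member barcode_id x cell type
    control_propensity: pd.Series     # per cell type
    samples: tuple[SampleSpec, ...]
    pool: ScreenPool
    params: SimParams
    seed: int

    def sampling_probs(self, cell_type: str | None) -> pd.Series:
        """Barcode sampling probabilities for a sorted-cell sample.

        ``None`` means the input pool: propensities are identically 1 and
        reads reflect pool composition only.
        """
        props = pd.Series(self.pool.input_proportions, dtype=float)
        if cell_type is not None:
            weights = self.propensity[cell_type].reindex(props.index)
            weights[self.pool.control_barcode_id] = self.control_propensity[cell_type]
            props = props * weights
        return props / props.sum()


def simulate_ground_truth(
    pool: ScreenPool,
    cell_types: Sequence[str],
    params: SimParams = SimParams(),
    seed: int = 0,
    n_mice: int = 3,
    depth: int = 10_000,
    library: Sequence[Formulation] | None = None,
    component_effects: Mapping[tuple[str, str], float] | None = None,
) -> GroundTruth:
    """Draw per-LNP, per-cell-type delivery propensities.

    ``component_effects`` maps (axis, level) to a multiplier applied to the
    propensity of every LNP carrying that level (requires ``library``), e.g.
    ``{("ionizable_lipid", "PPZ-A10"): 10.0}`` for a strong structure–function
    signal. The control weight is set to ``control_factor`` times the minimum
    LNP weight in each cell type, so the naked barcode is the weakest
    deliverer by construction. Deterministic per seed.
    """
    if not cell_types:
        raise ValueError("need at least one cell type")
    if n_mice < 1 or depth < 0:
        raise ValueError("n_mice must be >= 1 and depth >= 0")
    rng = np.random.default_rng(seed)
    members = list(pool.member_barcodes)
    prop = pd.DataFrame(
        np.exp(rng.normal(0.0, params.propensity_sdlog, (len(members), len(cell_types)))),
        index=members,
        columns=list(cell_types),
    )
    if component_effects:
        if library is None:
            raise ValueError("component_effects requires the formulation library")
        by_barcode = {f.barcode_id: f for f in library}
        for (axis, level), mult in component_effects.items():
            if mult <= 0:
                raise ValueError("component effect multipliers must be positive")
            hit = [b for b in members if by_barcode[b].component(axis) == level]
            prop.loc[hit] *= mult
    control = params.control_factor * prop.min(axis=0)
    samples = tuple(
        SampleSpec(
            sample_id=f"{ct}_m{m + 1}",
            mouse=f"m{m + 1}",
            cell_type=ct,
            depth=depth,
        )
        for ct in cell_types
        for m in range(n_mice)
    )
    return GroundTruth(
        propensity=prop,
        control_propensity=control,
        samples=samples,
        pool=pool,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Simulated reads plus the molecule-level truth table.

    ``molecules`` has one row per sampled molecule (barcode_id, umi, reads);
    ``records`` are (read_id, sequence) pairs in emission order.
    """

    sample_id: str
    records: list[tuple[str, str]]
    molecules: pd.DataFrame
    quality_char: str = "I"

    @property
    def true_read_counts(self) -> pd.Series:
        if self.molecules.empty:
            return pd.Series(dtype=int)
        return self.molecules.groupby("barcode_id")["reads"].sum()

    @property
    def true_molecule_counts(self) -> pd.Series:
        """Distinct (barcode, UMI) pairs actually emitted per barcode."""
        seen = self.molecules[self.molecules.reads > 0]
        if seen.empty:
            return pd.Series(dtype=int)
        return seen.groupby("barcode_id")["umi"].nunique()

    def write_fastq(self, path: str | Path) -> Path:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for rid, seq in self.records:
                fh.write(f"@{rid}\n{seq}\n+\n{self.quality_char * len(seq)}\n")
        return path


def _random_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(BASES[i] for i in row) for row in draws]


def _inject_errors(rng: np.random.Generator, seq: str, k: int) -> str:
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _simulate_reads(
    sample_id: str,
    probs: pd.Series,
    scaffolds: Mapping[str, BarcodeScaffold],
    primer_set: PrimerSet,
    depth: int,
    rng: np.random.Generator,
    params: SimParams,
) -> ReadSet:
    missing = [b for b in probs.index if b not in scaffolds]
    if missing:
        raise ValueError(f"no scaffold for pool barcodes: {missing}")
    empty_mols = pd.DataFrame(columns=["barcode_id", "umi", "reads"])
    if depth == 0:
        logger.warning("sample %s simulated at zero depth: empty FASTQ", sample_id)
        return ReadSet(sample_id, [], empty_mols, params.quality_char)

    n_molecules = max(1, int(depth // params.reads_per_molecule))
    mol_counts = rng.multinomial(n_molecules, probs.to_numpy())
    mol_barcodes: list[str] = []
    mol_seqs: list[str] = []
    mol_umis: list[str] = []
    for bid, m in zip(probs.index, mol_counts):
        if m == 0:
            continue
        scaffold = scaffolds[bid]
        for umi in _random_umis(rng, int(m), scaffold.segment("umi7").count("N") or 7):
            mol_barcodes.append(bid)
            mol_umis.append(umi)
            mol_seqs.append(scaffold.with_umi(umi))

    if params.pcr_bias_sd > 0:
        weights = rng.lognormal(0.0, params.pcr_bias_sd, len(mol_seqs))
    else:
        weights = np.ones(len(mol_seqs))
    read_counts = rng.multinomial(depth, weights / weights.sum())

    staggers = primer_set.fwd_staggers
    stag_idx = rng.integers(0, len(staggers), size=depth)
    stag_lens = np.array([len(s) for s in staggers])
    scaffold_len = len(mol_seqs[0])
    read_lens = scaffold_len + stag_lens[stag_idx]
    if params.error_rate > 0:
        n_errors = rng.binomial(read_lens, params.error_rate)
    else:
        n_errors = np.zeros(depth, dtype=int)

    records: list[tuple[str, str]] = []
    r = 0
    for mi, (mseq, count) in enumerate(zip(mol_seqs, read_counts)):
        for _ in range(int(count)):
            seq = staggers[stag_idx[r]] + mseq
            if n_errors[r]:
                seq = _inject_errors(rng, seq, int(n_errors[r]))
            records.append((f"{sample_id}:r{r}:{mol_barcodes[mi]}:{mol_umis[mi]}", seq))
            r += 1
    molecules = pd.DataFrame(
        {"barcode_id": mol_barcodes, "umi": mol_umis, "reads": read_counts.astype(int)}
    )
    return ReadSet(sample_id, records, molecules, params.quality_char)


def simulate_sample_reads(
    truth: GroundTruth,
    sample: SampleSpec | str,
    scaffolds: Mapping[str, BarcodeScaffold],
    primer_set: PrimerSet,
    seed: int,
    depth: int | None = None,
) -> ReadSet:
    """Simulate one sorted-cell sample's FASTQ reads.

    Sampling probabilities are input proportion x the sample cell type's
    propensity, renormalized.
    """
    if isinstance(sample, str):
        matches = [s for s in truth.samples if s.sample_id == sample]
        if not matches:
            raise KeyError(f"unknown sample {sample!r}")
        sample = matches[0]
    probs = truth.sampling_probs(sample.cell_type)
    rng = np.random.default_rng(seed)
    return _simulate_reads(
        sample.sample_id, probs, scaffolds, primer_set,
        depth if depth is not None else sample.depth, rng, truth.params,
    )


def simulate_input_sample(
    pool: ScreenPool,
    scaffolds: Mapping[str, BarcodeScaffold],
    primer_set: PrimerSet,
    depth: int,
    seed: int,
    params: SimParams = SimParams(),
) -> ReadSet:
    """Simulate the sequenced injected mixture (propensities identically 1)."""
    probs = pd.Series(pool.input_proportions, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    return _simulate_reads("input", probs, scaffolds, primer_set, depth, rng, params)


def simulate_sample_counts(
    truth: GroundTruth,
    sample: SampleSpec | str,
    seed: int,
    depth: int | None = None,
):
    """Counts-level shortcut: multinomial barcode counts without read synthesis.

    Skips PCR bias, staggering, and sequencing error; raw read counts are
    drawn directly from the sample's sampling probabilities and distinct-UMI
    counts from the molecule layer. Useful for many-seed Monte-Carlo studies
    of the downstream statistics.
    """
    from .counting import CountsTable

    if isinstance(sample, str):
        sample = next(s for s in truth.samples if s.sample_id == sample)
    probs = truth.sampling_probs(sample.cell_type)
    rng = np.random.default_rng(seed)
    n = depth if depth is not None else sample.depth
    raw = rng.multinomial(n, probs.to_numpy())
    n_molecules = max(1, int(n // truth.params.reads_per_molecule))
    mols = rng.multinomial(n_molecules, probs.to_numpy())
    df = pd.DataFrame(
        {"raw_reads": raw, "distinct_umis": np.minimum(mols, raw)},
        index=pd.Index(probs.index, name="barcode_id"),
    )
    return CountsTable(
        sample_id=sample.sample_id, counts=df, unassigned_reads=0, total_reads=int(n)
    )


def simulate_input_counts(pool: ScreenPool, depth: int, seed: int,
                          params: SimParams = SimParams()):
    """Counts-level shortcut for the input pool sample."""
    from .counting import CountsTable

    probs = pd.Series(pool.input_proportions, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    raw = rng.multinomial(depth, probs.to_numpy())
    df = pd.DataFrame(
        {"raw_reads": raw, "distinct_umis": raw},
        index=pd.Index(probs.index, name="barcode_id"),
    )
    return CountsTable(sample_id="input", counts=df, unassigned_reads=0,
                       total_reads=int(depth))


# ---------------------------------------------------------------------------
# Synthetic QC tables
# ---------------------------------------------------------------------------


def simulate_qc_table(
    formulations: Sequence[Formulation],
    seed: int = 0,
    n_pass: int | None = None,
) -> list[QCRecord]:
    """Generate a synthetic DLS QC table for a formulation library.

    No per-particle QC measurements are published for the screen this
    emulates, so the table is synthetic. With ``n_pass`` given, exactly that
    many formulations are drawn to pass (diameter uniform in (40, 180) nm,
    monodisperse); the rest fail by oversizing, undersizing, or
    polydispersity. Without ``n_pass``, diameters are log-normal around
    110 nm and monodispersity is Bernoulli(0.7), so the pass count is
    emergent.
    """
    rng = np.random.default_rng(seed)
    n = len(formulations)
    records: list[QCRecord] = []
    if n_pass is not None:
        if not 0 <= n_pass <= n:
            raise ValueError(f"n_pass must be in [0, {n}]")
        pass_idx = set(rng.choice(n, size=n_pass, replace=False).tolist())
        for i, f in enumerate(formulations):
            if i in pass_idx:
                records.append(
                    QCRecord(f.lnp_id, round(float(rng.uniform(40, 180)), 1), True,
                             round(float(rng.uniform(0.05, 0.2)), 3))
                )
            else:
                mode = rng.integers(0, 3)
                if mode == 0:      # aggregated / oversized
                    records.append(
                        QCRecord(f.lnp_id, round(float(rng.uniform(210, 450)), 1), True,
                                 round(float(rng.uniform(0.05, 0.3)), 3))
                    )
                elif mode == 1:    # undersized
                    records.append(
                        QCRecord(f.lnp_id, round(float(rng.uniform(5, 18)), 1), True,
                                 round(float(rng.uniform(0.05, 0.3)), 3))
                    )
                else:              # unstable autocorrelation
                    records.append(
                        QCRecord(f.lnp_id, round(float(rng.uniform(60, 190)), 1), False,
                                 round(float(rng.uniform(0.35, 0.6)), 3))
                    )
    else:
        for f in formulations:
            d = round(float(rng.lognormal(np.log(110.0), 0.45)), 1)
            mono = bool(rng.random() < 0.7)
            pdi = round(float(rng.uniform(0.05, 0.25) if mono else rng.uniform(0.35, 0.6)), 3)
            records.append(QCRecord(f.lnp_id, d, mono, pdi))
    return records


def samples_to_frame(samples: Sequence[SampleSpec],
                     fastq_paths: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "mouse": [s.mouse for s in samples],
            "tissue": [s.tissue for s in samples],
            "cell_type": [s.cell_type for s in samples],
            "depth": [s.depth for s in samples],
        }
    )
    if fastq_paths is not None:
        df["fastq"] = [fastq_paths[s.sample_id] for s in samples]
    return df


def samples_from_frame(df: pd.DataFrame) -> list[SampleSpec]:
    return [
        SampleSpec(
            sample_id=row.sample_id,
            mouse=str(row.mouse),
            cell_type=row.cell_type,
            tissue="" if pd.isna(row.tissue) else str(row.tissue),
            depth=int(row.depth),
        )
        for row in df.itertuples()
    ]
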