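"""Synthetic inputs: paired reads over repeat haplotypes and HD cohorts.

The read simulator emulates 75 bp paired-end exome sequencing over the
repeat locus: uniform fragment sampling per haplotype, Gaussian insert
sizes, optional uniform substitution errors.  The cohort simulator draws
diploid repeat genotypes from the allele-frequency inventory under
Hardy-Weinberg equilibrium, gives each individual a residual age at
motor onset with a linear repeat-sum effect plus normal noise, and
optionally applies sigmoid extreme-residual selection by accept/reject.
Defaults are the study conditions: 75 bp pairs at 30x, n = 610,
sigma = 7.02 y, selection (R_thr = 17.6 y, Delta = 3.30 y), effect
beta1 = -1.0 y per hexamer on the repeat sum, and a tag marker that
co-occurs with the three-repeat allele at 99% fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .caller import LocusRead
from .locus import ALLELES, RepeatLocus, allele_frequencies, build_allele_sequence
from .onset import LangbehnModel, SelectionModel, selection_function

__all__ = [
    "ReadSimConfig",
    "CohortSimConfig",
    "simulate_reads",
    "simulate_cohort",
    "simulate_selected_residuals",
    "end_to_end_fixture",
    "deletion_worked_example",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 75
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        arr[i] = rng.choice(bases[bases != arr[i]])
    return arr.tobytes().decode()


def simulate_reads(
    hap_a: str,
    hap_b: str,
    config: ReadSimConfig = ReadSimConfig(),
    rng: np.random.Generator | None = None,
    sample: str = "S0",
) -> tuple[list[LocusRead], dict[str, str]]:
    """Paired reads from a diploid haplotype pair (50:50 allele balance).

    Returns the reads (forward-strand sequences, as stored in SAM) and a
    truth record mapping read name to its source haplotype ("A"/"B").
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rl = config.read_length
    reads: list[LocusRead] = []
    truth: dict[str, str] = {}
    per_read = 2 if config.paired else 1
    for hap_label, hap in (("A", hap_a), ("B", hap_b)):
        if rl > len(hap):
            raise ValueError("read longer than haplotype")
        n_frag = int(round(config.coverage / 2 * len(hap) / (per_read * rl)))
        for k in range(n_frag):
            frag_len = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            frag_len = min(max(frag_len, rl), len(hap))
            start = int(rng.integers(0, len(hap) - frag_len + 1))
            name = f"{sample}:{hap_label}:{k}"
            truth[name] = hap_label
            r1 = _add_errors(hap[start : start + rl], config.error_rate, rng)
            reads.append(LocusRead(name, r1, 1, sample, start))
            if config.paired:
                end = start + frag_len
                r2 = _add_errors(hap[end - rl : end], config.error_rate, rng)
                reads.append(LocusRead(name, r2, 2, sample, end - rl))
    return reads, truth


@dataclass(frozen=True)
class CohortSimConfig:
    n: int = 610
    allele_freq: dict = field(default_factory=allele_frequencies)
    cag_min: int = 40
    cag_max: int = 50
    beta0: float = 0.0
    beta1: float = -1.0          # years per hexamer, on the centred repeat sum
    sigma: float = 7.02          # population residual SD (years)
    selection: SelectionModel | None = field(
        default_factory=lambda: SelectionModel(7.02, 17.6, 3.30)
    )
    marker_fidelity: float = 0.99
    keep_unselected: bool = False
    seed: int = 0


def _draw_alleles(freq: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    names = sorted(freq)
    p = np.array([freq[k] for k in names], dtype=float)
    p /= p.sum()
    return np.asarray(names)[rng.choice(len(names), size=n, p=p)]


def simulate_cohort(
    config: CohortSimConfig = CohortSimConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cohort table with genotypes, residuals, onsets and selection flags.

    The repeat effect acts on the population-centred repeat sum so that
    ``beta0`` keeps its meaning as the mean residual.  Selection keeps an
    individual with probability S(R); sampling continues until ``n``
    individuals are accepted.  The tag-marker allele copies the A2
    indicator with probability ``marker_fidelity`` and is otherwise an
    independent draw at the A2 frequency, which makes the dosage/A2-count
    correlation equal the fidelity.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    freq = dict(config.allele_freq)
    qtr_of = {k: ALLELES[k].qtr_units for k in freq}
    total = sum(freq.values())
    mean_sum = 2 * sum(freq[k] / total * qtr_of[k] for k in freq)
    onset_model = LangbehnModel()
    sel = config.selection

    chunks = []
    kept = 0
    attempts = 0
    target = config.n
    while kept < target:
        m = max(1024, 2 * (target - kept))
        a = _draw_alleles(freq, m, rng)
        b = _draw_alleles(freq, m, rng)
        qa = np.vectorize(qtr_of.get)(a)
        qb = np.vectorize(qtr_of.get)(b)
        nsum = qa + qb
        R = (
            config.beta0
            + config.beta1 * (nsum - mean_sum)
            + rng.normal(0.0, config.sigma, size=m)
        )
        if sel is None:
            selected = np.ones(m, dtype=bool)
        else:
            selected = rng.random(m) < selection_function(R, sel)
        cag = rng.integers(config.cag_min, config.cag_max + 1, size=m)
        fa = np.where(
            rng.random(m) < config.marker_fidelity,
            (a == "A2").astype(int),
            (rng.random(m) < freq.get("A2", 0.0) / total).astype(int),
        )
        fb = np.where(
            rng.random(m) < config.marker_fidelity,
            (b == "A2").astype(int),
            (rng.random(m) < freq.get("A2", 0.0) / total).astype(int),
        )
        df = pd.DataFrame(
            {
                "allele_a": a,
                "allele_b": b,
                "cag": cag,
                "qtr_a": qa,
                "qtr_b": qb,
                "str_a": [ALLELES[x].str_units for x in a],
                "str_b": [ALLELES[x].str_units for x in b],
                "residual": R,
                "marker_dosage": fa + fb,
                "selected": selected,
            }
        )
        attempts += m
        if config.keep_unselected:
            chunks.append(df)
            kept += int(selected.sum())
        else:
            chunks.append(df[selected])
            kept += int(selected.sum())
        if attempts > 200 and kept / attempts < 1e-4:
            raise RuntimeError(
                "selection acceptance rate below 1e-4; relax the selection model"
            )
    out = pd.concat(chunks, ignore_index=True)
    if not config.keep_unselected:
        out = out.iloc[:target].copy()
    else:
        keep_rows = np.nonzero(out["selected"].to_numpy())[0]
        out = out.iloc[: keep_rows[target - 1] + 1].copy()
    out["onset"] = onset_model.expected_onset(out["cag"].to_numpy()) + out[
        "residual"
    ].to_numpy()
    out.insert(0, "id", [f"I{i:05d}" for i in range(len(out))])
    return out.reset_index(drop=True)


def simulate_selected_residuals(
    n: int,
    model: SelectionModel,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Residuals from the selected-population density p_N(R)S(R)/Z."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    out: list[np.ndarray] = []
    kept = 0
    while kept < n:
        m = max(4096, 4 * (n - kept))
        r = rng.normal(0.0, model.sigma, size=m)
        acc = rng.random(m) < selection_function(r, model)
        out.append(r[acc])
        kept += int(acc.sum())
    return np.concatenate(out)[:n]


def end_to_end_fixture(
    seed: int = 0,
    n: int = 60,
    read_config: ReadSimConfig | None = None,
    cohort_config: CohortSimConfig | None = None,
    locus: RepeatLocus | None = None,
):
    """Coupled reads + truth genotypes + cohort table for pipeline tests.

    Each cohort individual gets its own simulated read set over its two
    allele haplotypes, so the caller's genotype table can feed the
    association machinery directly.
    """
    locus = locus or RepeatLocus()
    cohort_config = cohort_config or CohortSimConfig(n=n, seed=seed)
    if cohort_config.n != n:
        cohort_config = replace(cohort_config, n=n)
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(cohort_config, rng)
    read_config = read_config or ReadSimConfig()
    haps = {k: build_allele_sequence(ALLELES[k], locus) for k in ALLELES}
    sample_reads: dict[str, list[LocusRead]] = {}
    truth: dict[str, tuple[str, str]] = {}
    for _, row in cohort.iterrows():
        sid = row["id"]
        reads, _ = simulate_reads(
            haps[row["allele_a"]], haps[row["allele_b"]], read_config, rng, sid
        )
        sample_reads[sid] = reads
        truth[sid] = (row["allele_a"], row["allele_b"])
    return sample_reads, truth, cohort


def deletion_worked_example() -> tuple[str, str, dict]:
    """A read/window pair where a 3-hexamer deletion competes with mismatches.

    The window carries a periodic 18-mer region (a repeat in miniature)
    with two engineered period-breaking bases.  The read comes from a
    haplotype missing one 18 bp period.  The gapless alignment then has
    exactly m = 2 mismatches (M = 2), while the correct path has one
    deletion gap of height 18 between pieces of length 36 and 39
    (M = 18 * exp(5 - 36) ~ 6.2e-13).
    """
    rng = np.random.default_rng(42)
    left = "".join(rng.choice(list("ACGT"), size=36))
    unit18 = "ACGTACGGTTCAGCCTGA"
    win = list(left + unit18 * 3 + unit18[:3])
    # break the periodicity so the deletion breakpoints are pinned:
    # positions 54/72/90 share a new base (one mismatch pair at 36 vs 54),
    # and position 92 breaks the final pair (74 vs 92).
    for p in (54, 72, 90):
        win[p] = "G" if win[p] != "G" else "T"
    win[92] = "C" if win[92] != "C" else "A"
    if win[35] == win[53]:
        win[35] = "A" if win[53] != "A" else "C"
    window = "".join(win)
    read = window[:36] + window[54:93]
    expected = {
        "gapless_m": 2,
        "gapless_M": 2.0,
        "deletion": {"delta": 18, "flank_min": 36},
        "deletion_M": 18 * float(np.exp(5 - 36)),
    }
    return read, window, expected
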