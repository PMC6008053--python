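"""Synthetic dynamic-SILAC data with known ground truth.

The generator emulates the study design downstream stages expect: a
light-to-heavy medium switch leaving a residual light pool (default
heavy:light 4:1, i.e. p_heavy = 0.8), sampling at 0/1/3/7 days in three
biological replicates with triplicate injections, and a right-skewed
log-normal half-life distribution (default median 5.4 days) spanning
<1 to >20 days.

Forward model per peptide measurement at time t: the pre-existing (old)
fraction is f = exp(-k_true * t). Nascent molecules draw each labelable
Arg/Lys heavy independently with probability p_heavy. The visible light
channel contains old molecules plus all-light nascent molecules; the
visible heavy channel contains all-heavy nascent molecules; mixed-label
species of missed-cleavage peptides are invisible to the ratio but are
tallied into the label-count table as LH detections. The emitted ratio is
the heavy/light quotient under multiplicative log-normal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigError
from .types import LABEL_COUNT_COLUMNS, PEPTIDE_COLUMNS

__all__ = [
    "TrueProteome",
    "generate_proteome",
    "simulate_silac_experiment",
    "simulate_label_counts",
    "simulate_puncta",
]

# sub-stream tags so each table draws from its own named stream
_STREAM_PROTEOME = 11
_STREAM_RATIOS = 23
_STREAM_COUNTS = 37
_STREAM_PUNCTA = 53

_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R reserved for termini


@dataclass
class TrueProteome:
    """Ground-truth proteome: per-condition rate constants and peptides."""

    #: protein_group, condition, k_true, half_life_true_days, complex_id
    rates: pd.DataFrame
    #: protein_group, sequence, missed_cleavages, detectability
    peptides: pd.DataFrame

    def k_map(self, condition: str) -> dict[str, float]:
        sub = self.rates[self.rates["condition"] == condition]
        return dict(zip(sub["protein_group"], sub["k_true"]))


def _tryptic_sequences(n: int, missed: np.ndarray, rng) -> list[str]:
    """Random tryptic-looking peptide sequences, unique, with the requested
    number of internal K/R (missed cleavages)."""
    lengths = rng.integers(8, 24, size=n)
    seen: set[str] = set()
    out = []
    for i in range(n):
        body = "".join(rng.choice(_RESIDUES, size=lengths[i]))
        mc = int(missed[i])
        if mc:
            positions = rng.choice(np.arange(1, lengths[i]), size=mc, replace=False)
            chars = list(body)
            for pos in positions:
                chars[pos] = "K" if rng.random() < 0.5 else "R"
            body = "".join(chars)
        seq = body + ("K" if rng.random() < 0.5 else "R")
        while seq in seen:  # vanishingly rare
            seq = seq[:-1] + "".join(rng.choice(_RESIDUES, size=1)) + seq[-1]
        seen.add(seq)
        out.append(seq)
    return out


def generate_proteome(config: SimulationConfig, seed: int | None = None) -> TrueProteome:
    """Draw a ground-truth proteome from the configured distributions.

    Half-lives are log-normal with the configured median; proteins assigned
    to a complex share a common component on the log rate constant so that
    the within-complex correlation of log k equals ``complex_icc``.
    Condition rate constants are the reference times the configured
    multiplier. Deterministic given the seed.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_PROTEOME])
    n = config.n_proteins

    # complex assignment: disjoint blocks of the first proteins
    sizes = rng.integers(
        config.complex_size_range[0], config.complex_size_range[1] + 1,
        size=config.n_complexes,
    )
    if sizes.sum() > n:
        raise ConfigError(
            f"complex members ({int(sizes.sum())}) exceed n_proteins ({n})"
        )
    complex_id = np.array([""] * n, dtype=object)
    complex_index = np.full(n, -1)
    start = 0
    for j, size in enumerate(sizes):
        complex_id[start:start + size] = f"CPX{j:04d}"
        complex_index[start:start + size] = j
        start += size

    # shared + private standard-normal components on log half-life
    rho = config.complex_icc
    shared = rng.standard_normal(config.n_complexes) if config.n_complexes else np.empty(0)
    private = rng.standard_normal(n)
    z = private.copy()
    members = complex_index >= 0
    if members.any():
        z[members] = (
            math.sqrt(rho) * shared[complex_index[members]]
            + math.sqrt(1.0 - rho) * private[members]
        )
    t_half = config.halflife_median_days * np.exp(config.halflife_log_sd * z)
    k_ref = math.log(2.0) / t_half

    protein_group = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    frames = []
    for condition, mult in config.condition_multipliers.items():
        if mult <= 0:
            raise ConfigError(f"condition multiplier for {condition!r} must be > 0")
        k = k_ref * mult
        frames.append(
            pd.DataFrame(
                {
                    "protein_group": protein_group,
                    "condition": condition,
                    "k_true": k,
                    "half_life_true_days": math.log(2.0) / k,
                    "complex_id": complex_id,
                }
            )
        )
    rates = pd.concat(frames, ignore_index=True)

    n_pep = rng.geometric(1.0 / config.peptides_per_protein_mean, size=n)
    missed = (rng.random(int(n_pep.sum())) < config.missed_cleavage_prob).astype(int)
    detect = rng.uniform(*config.detectability_range, size=int(n_pep.sum()))
    peptides = pd.DataFrame(
        {
            "protein_group": np.repeat(protein_group, n_pep),
            "sequence": _tryptic_sequences(int(n_pep.sum()), missed, rng),
            "missed_cleavages": missed,
            "detectability": detect,
        }
    )
    return TrueProteome(rates=rates, peptides=peptides)


def simulate_label_counts(n_events: int, p_heavy: float, rng) -> tuple[int, int, int]:
    """Label species of ``n_events`` nascent missed-cleavage peptides.

    Each event carries two labelable residues, heavy independently with
    probability ``p_heavy``. Returns (LL, LH, HH) detection counts; LL is
    returned for bookkeeping but is unobservable in a real experiment.
    """
    p_l = 1.0 - p_heavy
    ll, lh, hh = rng.multinomial(
        n_events, [p_l * p_l, 2.0 * p_l * p_heavy, p_heavy * p_heavy]
    )
    return int(ll), int(lh), int(hh)


def simulate_silac_experiment(
    proteome: TrueProteome, config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the measured peptide table and per-sample label counts.

    Returns ``(peptide_table, label_counts, ground_truth)``. The peptide
    table and label counts use the canonical column layouts the readers
    produce; ground truth is the proteome's rates table.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_RATIOS])
    rng_counts = np.random.default_rng([seed, _STREAM_COUNTS])

    pep = proteome.peptides
    n_pep = len(pep)
    timepoints = np.asarray(config.timepoints, dtype=float)
    replicates = [f"R{i+1}" for i in range(config.n_replicates)]
    injections = [f"I{i+1}" for i in range(config.n_injections)]
    p_h = config.p_heavy
    p_l = 1.0 - p_h

    pep_k = {}  # condition -> per-peptide k_true
    for condition in config.condition_multipliers:
        k_map = proteome.k_map(condition)
        pep_k[condition] = pep["protein_group"].map(k_map).to_numpy()

    n_res_pep = pep["missed_cleavages"].to_numpy() + 1
    detect = pep["detectability"].to_numpy()
    frames = []
    count_rows = []
    for condition in config.condition_multipliers:
        k = pep_k[condition]
        for rep in replicates:
            for inj in injections:
                for t in timepoints:
                    f_old = np.exp(-k * t)
                    a = p_l**n_res_pep  # nascent all-light
                    b = p_h**n_res_pep  # nascent all-heavy
                    light = f_old + (1.0 - f_old) * a
                    heavy = (1.0 - f_old) * b
                    light_only = heavy <= 0.0
                    noise = (
                        np.exp(rng.normal(0.0, config.ratio_noise_log_sd, n_pep))
                        if config.ratio_noise_log_sd > 0
                        else 1.0
                    )
                    ratio = np.where(light_only, np.nan,
                                     heavy / light * noise)
                    keep = rng.random(n_pep) < detect * (1.0 - config.dropout_prob)
                    frames.append(
                        pd.DataFrame(
                            {
                                "sequence": pep["sequence"].to_numpy()[keep],
                                "protein_group": pep["protein_group"].to_numpy()[keep],
                                "missed_cleavages": pep["missed_cleavages"].to_numpy()[keep],
                                "ratio_HL": ratio[keep],
                                "light_only": light_only[keep],
                                "timepoint": t,
                                "replicate": rep,
                                "injection": inj,
                                "condition": condition,
                            }
                        )
                    )
                    if t > 0:
                        mc_mask = pep["missed_cleavages"].to_numpy() >= 1
                        if mc_mask.any():
                            nascent = float(np.mean(1.0 - f_old[mc_mask]))
                            expected = config.label_events_per_sample * nascent
                            n_events = int(rng_counts.poisson(expected))
                        else:
                            n_events = 0
                        _, lh, hh = simulate_label_counts(n_events, p_h, rng_counts)
                        count_rows.append((condition, rep, inj, t, lh, hh))

    peptide_table = pd.concat(frames, ignore_index=True)[list(PEPTIDE_COLUMNS)]
    label_counts = pd.DataFrame(count_rows, columns=list(LABEL_COUNT_COLUMNS))
    return peptide_table, label_counts, proteome.rates.copy()


def simulate_puncta(
    true_half_life: float,
    chase_days,
    n_cells: int,
    n0: float,
    seed: int = 0,
    target: str = "target",
) -> pd.DataFrame:
    """Poisson puncta counts per cell around an exponential mean decay.

    Per-cell counts at chase day t are Poisson with mean
    ``n0 * exp(-ln2 * t / true_half_life)``. Deterministic given the seed.
    """
    if true_half_life <= 0:
        raise ConfigError("true_half_life must be positive")
    if n0 <= 0:
        raise ConfigError("n0 must be positive")
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_PUNCTA])
    rows = []
    for day in chase_days:
        mean = n0 * math.exp(-math.log(2.0) * day / true_half_life)
        counts = rng.poisson(mean, size=n_cells)
        for i, count in enumerate(counts):
            rows.append((f"{target}_d{day:g}_c{i:03d}", float(day), int(count), target))
    return pd.DataFrame(
        rows, columns=["cell_id", "chase_days", "puncta_count", "target"]
    )
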