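import numpy as np
import pytest

from cargbend.simulate import SimulationConfig


@pytest.fixture
def noiseless_cfg():
    return SimulationConfig(seed=1, mobility_sigma=0.0, binding_sigma=0.0, circ_sigma=0.0)


@pytest.fixture
def default_cfg():
    return SimulationConfig(seed=1)


def brute_force_scan(seq_id, sequence, patterns, max_atypical, both_strands):
    """Independent position-by-position reference scanner.

    Checks every window of every pattern length on the requested strands by
    direct per-position set membership, with the same palindrome dedup rule
    as the package scanner (exact palindromes reported once, on "+").
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    results = []
    for pattern in patterns:
        k = len(pattern.positions)
        for i in range(len(sequence) - k + 1):
            window = sequence[i : i + k]
            rc = "".join(comp[b] for b in reversed(window))
            for strand in ("+", "-") if both_strands else ("+",):
                probe = window if strand == "+" else rc
                n = sum(
                    b not in allowed for b, allowed in zip(probe, pattern.positions)
                )
                if n > max_atypical:
                    continue
                if strand == "-" and probe == window:
                    continue  # exact palindrome already reported on "+"
                results.append(
                    (seq_id, i, i + k, strand, probe, pattern.name, n)
                )
    return sorted(results, key=lambda r: (r[1], r[3], r[5]))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
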