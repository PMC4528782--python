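"""Shared fixtures: deterministic synthetic panels for every stage."""

from __future__ import annotations

import numpy as np
import pytest

from umiamp.panel import Amplicon, Panel, Primer

TAG_BC = "AATGTACAGTATTGCGTTTTG"
TAG_NONBC = "CAAGCAGAAGACGGCATACGA"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_panel(
    n_amplicons: int = 2,
    insert_len: int = 80,
    primer_len: int = 20,
    barcode_length: int = 10,
    seed: int = 7,
    with_intervals: bool = False,
) -> Panel:
    """A synthetic panel with random primers and inserts.

    With ``with_intervals`` each amplicon gets a reference interval on its own
    contig with the primer start at coordinate 0 (the layout the alignment
    extraction tests use).
    """
    rng = np.random.default_rng(seed)
    amps = []
    for i in range(n_amplicons):
        amp_id = f"amp{i:03d}"
        primer = random_seq(rng, primer_len)
        insert = random_seq(rng, insert_len)
        interval = None
        if with_intervals:
            from umiamp.panel import ReferenceInterval

            interval = ReferenceInterval(amp_id, 0, primer_len + insert_len)
        amps.append(
            Amplicon(
                amplicon_id=amp_id,
                bc_primer=Primer(f"{amp_id}_bc", primer, "barcoded", TAG_BC),
                nonbc_primer=Primer(
                    f"{amp_id}_nonbc", random_seq(rng, primer_len), "non_barcoded", TAG_NONBC
                ),
                expected_barcode_length=barcode_length,
                reference_interval=interval,
                insert_sequence=insert,
            )
        )
    return Panel(amps, universal_tag_bc=TAG_BC, universal_tag_nonbc=TAG_NONBC)


@pytest.fixture
def small_panel() -> Panel:
    return make_panel(n_amplicons=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
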