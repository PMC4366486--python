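import numpy as np
import pytest

from ecospace.data_model import (
    EcologicalMode,
    GenusRecord,
    GeologicStage,
    Timescale,
    range_through,
)


@pytest.fixture
def five_stage_timescale() -> Timescale:
    """Five contiguous 10-Myr stages, 50-0 Ma, across two eras."""
    return Timescale(
        [
            GeologicStage("A", 50, 40, period="P1", era="Palaeozoic"),
            GeologicStage("B", 40, 30, period="P1", era="Palaeozoic"),
            GeologicStage("C", 30, 20, period="P2", era="Mesozoic"),
            GeologicStage("D", 20, 10, period="P2", era="Mesozoic"),
            GeologicStage("E", 10, 0, period="P3", era="Cenozoic"),
        ]
    )


def make_record(
    name: str,
    fad: str,
    lad: str,
    mode: tuple[int, int, int],
    timescale: Timescale,
    phylum: str = "Mollusca",
    class_: str = "Gastropoda",
) -> GenusRecord:
    return GenusRecord(
        taxon_name=name,
        phylum=phylum,
        class_=class_,
        fad_age=timescale.stage(fad).base_age,
        fad_int=fad,
        lad_age=timescale.stage(lad).top_age,
        lad_int=lad,
        mode=EcologicalMode(*mode),
    )


@pytest.fixture
def small_occurrences(five_stage_timescale):
    """Six genera over five stages with a small spread of modes."""
    ts = five_stage_timescale
    records = [
        make_record("Ga", "A", "C", (1, 1, 1), ts),
        make_record("Gb", "A", "E", (1, 1, 1), ts),
        make_record("Gc", "B", "B", (2, 1, 1), ts),
        make_record("Gd", "B", "D", (2, 2, 1), ts),
        make_record("Ge", "C", "E", (3, 2, 1), ts),
        make_record("Gf", "E", "E", (1, 1, 1), ts),
    ]
    return records, range_through(records, ts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
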