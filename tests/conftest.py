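import pytest

from neutralqol import CrossWalk, InstrumentDefinition, Item


def make_instrument(instrument_id, n_items, category="specific", stratum="non_rare"):
    if category == "generic":
        stratum = "not_applicable"
    return InstrumentDefinition(
        instrument_id=instrument_id,
        name=f"{instrument_id} questionnaire",
        category=category,
        stratum=stratum,
        items=[
            Item(item_id=f"{instrument_id}-i{k}", label=f"item {k}")
            for k in range(1, n_items + 1)
        ],
    )


@pytest.fixture
def specific10():
    return make_instrument("SPEC", 10)


@pytest.fixture
def generic8():
    return make_instrument("GEN", 8, category="generic")


@pytest.fixture
def walk4(specific10, generic8):
    """Four match pairs over four distinct specific and generic items."""
    return CrossWalk(
        specific_id="SPEC",
        generic_id="GEN",
        matches=[
            (f"SPEC-i{k}", f"GEN-i{k}") for k in range(1, 5)
        ],
    )
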