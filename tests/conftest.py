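import numpy as np
import pandas as pd
import pytest

from carbquality.ffq_engine import FFQItem, FrequencyResponse


@pytest.fixture
def toy_catalogue():
    """Three hand-specified items spanning grain/liquid/GI structure."""
    items = [
        FFQItem(
            item_id="bread", name="wholegrain bread", portion_g=60,
            energy_kcal=150, carb_g=25, fiber_g=4, protein_g=5, fat_g=1.5,
            mufa_g=0.5, pufa_g=0.4, sfa_g=0.3, glycaemic_index=52,
            is_grain=True, is_whole_grain=True, food_group="cereals",
        ),
        FFQItem(
            item_id="cola", name="sugar-sweetened cola", portion_g=330,
            energy_kcal=140, carb_g=35, fiber_g=0, protein_g=0, fat_g=0,
            glycaemic_index=90, is_liquid_carb=True, food_group="other",
        ),
        FFQItem(
            item_id="lentils", name="lentil stew", portion_g=200,
            energy_kcal=230, carb_g=30, fiber_g=8, protein_g=12, fat_g=3,
            mufa_g=1.2, pufa_g=0.8, sfa_g=0.6, glycaemic_index=32,
            food_group="legumes",
        ),
    ]
    return {it.item_id: it for it in items}


@pytest.fixture
def toy_responses():
    """Mixed frequencies over the toy catalogue: daily bread, weekly cola,
    2-4/week lentils."""
    return [
        FrequencyResponse("bread", "1/day"),
        FrequencyResponse("cola", "1/week"),
        FrequencyResponse("lentils", "2-4/week"),
    ]


def random_catalogue(rng, n_items):
    """Small random catalogue for oracle/property tests."""
    items = {}
    for k in range(n_items):
        carb = float(rng.uniform(0, 40))
        is_grain = bool(rng.random() < 0.4)
        items[f"i{k}"] = FFQItem(
            item_id=f"i{k}",
            portion_g=float(rng.uniform(20, 300)),
            energy_kcal=float(rng.uniform(20, 400)),
            carb_g=carb,
            fiber_g=float(rng.uniform(0, 8)),
            protein_g=float(rng.uniform(0, 20)),
            fat_g=float(rng.uniform(0, 15)),
            glycaemic_index=(
                float(rng.uniform(20, 110)) if carb > 0 and rng.random() < 0.85 else None
            ),
            is_grain=is_grain,
            is_whole_grain=bool(is_grain and rng.random() < 0.5),
            is_liquid_carb=bool(rng.random() < 0.15),
            food_group="other",
        )
    return items


def random_responses(rng, items):
    from carbquality.ffq_engine import FREQUENCY_LABELS

    return [
        FrequencyResponse(iid, FREQUENCY_LABELS[rng.integers(0, 9)])
        for iid in items
    ]
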