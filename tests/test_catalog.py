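"""Regimen catalog and classification rules."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gclot import classify_regimen, default_catalog
from gclot.catalog import Agent, Regimen, RegimenCatalog

CANONICAL_SETS = {
    # every regimen abbreviation used in the published pattern tables
    "S-1": {"s1"},
    "SOX": {"s1", "oxaliplatin"},
    "CapeOX": {"capecitabine", "oxaliplatin"},
    "DS": {"s1", "docetaxel"},
    "SP": {"s1", "cisplatin"},
    "XP": {"capecitabine", "cisplatin"},
    "FOLFOX": {"folinic_acid", "fluorouracil", "oxaliplatin"},
    "FOL + 5-FU": {"folinic_acid", "fluorouracil"},
    "FOL + 5-FU + cisplatin": {"folinic_acid", "fluorouracil", "cisplatin"},
    "FOL + 5-FU + PTX": {"folinic_acid", "fluorouracil", "paclitaxel"},
    "PTX + RAM": {"paclitaxel", "ramucirumab"},
    "nab-PTX + RAM": {"nab_paclitaxel", "ramucirumab"},
    "IRI + RAM": {"irinotecan", "ramucirumab"},
    "PTX": {"paclitaxel"},
    "nab-PTX": {"nab_paclitaxel"},
    "RAM": {"ramucirumab"},
    "DTX": {"docetaxel"},
    "IRI": {"irinotecan"},
    "NIV": {"nivolumab"},
    "PEM": {"pembrolizumab"},
    "FTD/TPI": {"trifluridine_tipiracil"},
}


@pytest.mark.parametrize("label,agents", sorted(CANONICAL_SETS.items()))
def test_every_published_label_is_producible(catalog, label, agents):
    assert classify_regimen(agents, catalog) == label


def test_fallback_label_joins_sorted_display_names(catalog):
    # capecitabine + oxaliplatin + irinotecan matches no catalog regimen
    assert (
        classify_regimen({"capecitabine", "oxaliplatin", "irinotecan"}, catalog)
        == "Cape + IRI + OX"
    )


def test_empty_set_and_her2_antibody_are_rejected(catalog):
    with pytest.raises(ValueError):
        classify_regimen(set(), catalog)
    with pytest.raises(ValueError):
        classify_regimen({"s1", "trastuzumab"}, catalog)
    with pytest.raises(KeyError):
        classify_regimen({"not_a_drug"}, catalog)


@settings(deadline=None, max_examples=50)
@given(st.permutations(["capecitabine", "oxaliplatin", "irinotecan", "s1"]))
def test_classification_is_order_and_duplication_invariant(perm):
    catalog = default_catalog()
    canonical = classify_regimen(set(perm), catalog)
    assert classify_regimen(frozenset(list(perm) + list(perm)), catalog) == canonical


def test_her2_antibody_cannot_enter_a_base_regimen_definition():
    agents = [
        Agent("a", "A", "other"),
        Agent("tmab", "T-mab", "tmab_tdxd"),
    ]
    with pytest.raises(ValueError, match="tmab"):
        RegimenCatalog(
            agents, [Regimen("A + T", frozenset({"a", "tmab"}), frozenset({"first_line"}))]
        )


def test_duplicate_regimen_agent_sets_rejected():
    agents = [Agent("a", "A", "other")]
    regs = [
        Regimen("X", frozenset({"a"}), frozenset({"first_line"})),
        Regimen("Y", frozenset({"a"}), frozenset({"second_line"})),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        RegimenCatalog(agents, regs)


def test_catalog_yaml_round_trip(tmp_path, catalog):
    path = tmp_path / "catalog.yaml"
    catalog.to_yaml(path)
    loaded = RegimenCatalog.from_yaml(path)
    assert loaded.to_dict() == catalog.to_dict()
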