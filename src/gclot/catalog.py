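"""Agent vocabulary and canonical regimen catalog.

The catalog plays the role of the guideline regimen dictionary: it maps an
agent code to a display abbreviation and pharmacological class, and an exact
agent set to a canonical regimen label (S-1, SOX, CapeOX, DS, SP, XP,
FOLFOX, PTX + RAM, ...).  HER2-directed antibodies (trastuzumab and
trastuzumab deruxtecan) are tagged ``tmab_tdxd`` and never appear inside a
base regimen definition; they are attached to lines separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import yaml

AGENT_CLASSES = frozenset(
    {
        "fluoropyrimidine",
        "platinum",
        "taxane",
        "ramucirumab",
        "immune_checkpoint",
        "tmab_tdxd",
        "other",
    }
)

REGIMEN_SETTINGS = frozenset({"adjuvant", "first_line", "second_line"})


@dataclass(frozen=True)
class Agent:
    code: str
    display: str
    agent_class: str

    def __post_init__(self) -> None:
        if self.agent_class not in AGENT_CLASSES:
            raise ValueError(f"unknown agent class {self.agent_class!r}")


@dataclass(frozen=True)
class Regimen:
    label: str
    agents: frozenset[str]
    settings: frozenset[str]
    recommended_since: date | None = None

    def __post_init__(self) -> None:
        if not self.agents:
            raise ValueError("regimen must contain at least one agent")
        unknown = self.settings - REGIMEN_SETTINGS
        if unknown:
            raise ValueError(f"unknown regimen settings {sorted(unknown)}")


class RegimenCatalog:
    """Lookup of agents by code and regimens by exact agent set."""

    def __init__(self, agents: list[Agent], regimens: list[Regimen]):
        self.agents: dict[str, Agent] = {a.code: a for a in agents}
        if len(self.agents) != len(agents):
            raise ValueError("duplicate agent codes")
        self.regimens: list[Regimen] = list(regimens)
        self._by_set: dict[frozenset[str], Regimen] = {}
        for r in regimens:
            if r.agents in self._by_set:
                raise ValueError(f"duplicate regimen agent set {sorted(r.agents)}")
            for code in r.agents:
                if code not in self.agents:
                    raise ValueError(f"regimen {r.label}: unknown agent {code}")
                if self.agents[code].agent_class == "tmab_tdxd":
                    raise ValueError(
                        f"regimen {r.label}: tmab_tdxd agent {code} may not appear "
                        "in a base regimen definition"
                    )
            self._by_set[r.agents] = r

    # -- queries ----------------------------------------------------------

    def has_agent(self, code: str) -> bool:
        return code in self.agents

    def is_tmab(self, code: str) -> bool:
        return self.agents[code].agent_class == "tmab_tdxd"

    def display(self, code: str) -> str:
        return self.agents[code].display

    def exact_regimen(self, agent_set: frozenset[str] | set[str]) -> Regimen | None:
        return self._by_set.get(frozenset(agent_set))

    def regimens_with_setting(self, setting: str) -> list[Regimen]:
        return [r for r in self.regimens if setting in r.settings]

    def regimen_by_label(self, label: str) -> Regimen:
        for r in self.regimens:
            if r.label == label:
                return r
        raise KeyError(label)

    def largest_subset_regimen(
        self, agent_set: set[str] | frozenset[str], setting: str
    ) -> Regimen | None:
        """Largest catalog regimen with `setting` whose agents all lie in
        `agent_set` (exact matches included)."""
        best: Regimen | None = None
        for r in self.regimens_with_setting(setting):
            if r.agents <= frozenset(agent_set):
                if best is None or len(r.agents) > len(best.agents) or (
                    len(r.agents) == len(best.agents) and r.label < best.label
                ):
                    best = r
        return best

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "agents": [
                {"code": a.code, "display": a.display, "class": a.agent_class}
                for a in self.agents.values()
            ],
            "regimens": [
                {
                    "label": r.label,
                    "agents": sorted(r.agents),
                    "settings": sorted(r.settings),
                    "recommended_since": (
                        r.recommended_since.isoformat() if r.recommended_since else None
                    ),
                }
                for r in self.regimens
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimenCatalog":
        agents = [Agent(a["code"], a["display"], a["class"]) for a in d["agents"]]
        regimens = [
            Regimen(
                r["label"],
                frozenset(r["agents"]),
                frozenset(r["settings"]),
                date.fromisoformat(r["recommended_since"])
                if r.get("recommended_since")
                else None,
            )
            for r in d["regimens"]
        ]
        return cls(agents, regimens)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RegimenCatalog":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def classify_regimen(agent_set: set[str] | frozenset[str], catalog: RegimenCatalog) -> str:
    """Canonical regimen label for a set of non-HER2-antibody agent codes.

    Exact catalog matches get the canonical label; anything else falls back
    to the alphabetically sorted display names joined with " + ", which is
    deterministic and order/duplication invariant.
    """
    agent_set = frozenset(agent_set)
    if not agent_set:
        raise ValueError("agent_set must be non-empty")
    for code in agent_set:
        if not catalog.has_agent(code):
            raise KeyError(f"unknown agent code {code!r}")
        if catalog.is_tmab(code):
            raise ValueError(
                f"HER2 antibody {code!r} must be attached to a line, not classified "
                "as part of a base regimen"
            )
    reg = catalog.exact_regimen(agent_set)
    if reg is not None:
        return reg.label
    return " + ".join(sorted(catalog.display(c) for c in agent_set))


def default_catalog() -> RegimenCatalog:
    """Catalog covering the guideline regimens used in gastric cancer."""
    A = Agent
    agents = [
        A("s1", "S-1", "fluoropyrimidine"),
        A("capecitabine", "Cape", "fluoropyrimidine"),
        A("fluorouracil", "5-FU", "fluoropyrimidine"),
        A("folinic_acid", "FLN", "other"),
        A("oxaliplatin", "OX", "platinum"),
        A("cisplatin", "CDDP", "platinum"),
        A("docetaxel", "DTX", "taxane"),
        A("paclitaxel", "PTX", "taxane"),
        A("nab_paclitaxel", "nab-PTX", "taxane"),
        A("ramucirumab", "RAM", "ramucirumab"),
        A("irinotecan", "IRI", "other"),
        A("nivolumab", "NIV", "immune_checkpoint"),
        A("pembrolizumab", "PEM", "immune_checkpoint"),
        A("trifluridine_tipiracil", "FTD/TPI", "other"),
        A("trastuzumab", "T-mab", "tmab_tdxd"),
        A("trastuzumab_deruxtecan", "T-DXd", "tmab_tdxd"),
    ]
    R = Regimen
    fs = frozenset
    regimens = [
        R("S-1", fs({"s1"}), fs({"adjuvant", "first_line"})),
        R("SOX", fs({"s1", "oxaliplatin"}), fs({"adjuvant", "first_line"}),
          date(2016, 6, 1)),
        R("CapeOX", fs({"capecitabine", "oxaliplatin"}),
          fs({"adjuvant", "first_line"}), date(2016, 6, 1)),
        R("DS", fs({"s1", "docetaxel"}), fs({"adjuvant", "first_line"}),
          date(2019, 9, 1)),
        R("SP", fs({"s1", "cisplatin"}), fs({"first_line"})),
        R("XP", fs({"capecitabine", "cisplatin"}), fs({"first_line"})),
        R("FOLFOX", fs({"folinic_acid", "fluorouracil", "oxaliplatin"}),
          fs({"first_line"})),
        R("FOL + 5-FU", fs({"folinic_acid", "fluorouracil"}), fs({"first_line"})),
        R("FOL + 5-FU + cisplatin",
          fs({"folinic_acid", "fluorouracil", "cisplatin"}), fs({"first_line"})),
        R("FOL + 5-FU + PTX",
          fs({"folinic_acid", "fluorouracil", "paclitaxel"}), fs({"first_line"})),
        R("PTX + RAM", fs({"paclitaxel", "ramucirumab"}),
          fs({"first_line", "second_line"}), date(2015, 10, 1)),
        R("nab-PTX + RAM", fs({"nab_paclitaxel", "ramucirumab"}),
          fs({"first_line", "second_line"}), date(2015, 10, 1)),
        R("IRI + RAM", fs({"irinotecan", "ramucirumab"}), fs({"second_line"}),
          date(2015, 10, 1)),
        R("PTX", fs({"paclitaxel"}), fs({"first_line", "second_line"})),
        R("nab-PTX", fs({"nab_paclitaxel"}), fs({"first_line", "second_line"})),
        R("RAM", fs({"ramucirumab"}), fs({"first_line", "second_line"}),
          date(2015, 10, 1)),
        R("DTX", fs({"docetaxel"}), fs({"first_line", "second_line"})),
        R("IRI", fs({"irinotecan"}), fs({"first_line", "second_line"})),
        R("NIV", fs({"nivolumab"}), fs({"second_line"}), date(2017, 9, 22)),
        R("PEM", fs({"pembrolizumab"}), fs({"first_line", "second_line"})),
        R("FTD/TPI", fs({"trifluridine_tipiracil"}), fs({"second_line"})),
    ]
    return RegimenCatalog(agents, regimens)


#: roll-up used for era-level adjuvant pattern reporting
FLUORO_OXALIPLATIN_ROLLUP = {
    "SOX": "Fluoropyrimidine + oxaliplatin",
    "CapeOX": "Fluoropyrimidine + oxaliplatin",
}
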