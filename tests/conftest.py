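import pytest

from polabr.faers_tables import (DemoRecord, DrugEntry, IndicationEntry,
                                 OutcomeEntry, QuarterBundle, ReactionEntry)
from polabr.synthetic_faers import GeneratorConfig, generate


def demo_row(primaryid, caseid, fda_dt, caseversion=1, **kw):
    return DemoRecord(primaryid=str(primaryid), caseid=str(caseid),
                      caseversion=caseversion, fda_dt=fda_dt, **kw)


def bundle(demo=(), drug=(), reac=(), outc=(), indi=(), label="2021Q1"):
    return QuarterBundle(demo=list(demo), drug=list(drug), reac=list(reac),
                         outc=list(outc), indi=list(indi), label=label)


def regimen_drugs(primaryid, roles=("PS", "SS", "SS")):
    names = ("polatuzumab vedotin", "bendamustine", "rituximab")
    return [DrugEntry(str(primaryid), i + 1, role, name.upper(), name)
            for i, (role, name) in enumerate(zip(roles, names))]


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic world: 4,000 reports, 5% cohort, one injected
    signal at true ROR 5."""
    return GeneratorConfig(n_reports=4000, cohort_fraction=0.05,
                           partial_regimen_fraction=0.03, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate(small_config)


# re-export record constructors for terse test bodies
DemoRecord = DemoRecord
DrugEntry = DrugEntry
ReactionEntry = ReactionEntry
OutcomeEntry = OutcomeEntry
IndicationEntry = IndicationEntry
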