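import numpy as np
import pytest

from glyzip.core import COVERAGE_LEVELS, MotifInstance, ProteinRecord, TMFeature

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_motif(rng: np.random.Generator) -> str:
    return "G" + "".join(rng.choice(list(AA), size=3)) + "G"


def random_instances(rng: np.random.Generator, n: int, n_types: int = 30) -> list[MotifInstance]:
    types = list({random_motif(rng) for _ in range(n_types)})
    return [
        MotifInstance(
            protein_ref=f"P{int(rng.integers(10)):02d}",
            motif=types[int(rng.integers(len(types)))],
            start=int(rng.integers(1, 500)),
            tm_coverage=int(rng.choice(COVERAGE_LEVELS)),
        )
        for _ in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "GAAAGAAAG", organism="org_a"),
        ProteinRecord(
            "P2",
            "MMGLLLGMMM",
            organism="org_a",
            tm_features=[TMFeature(1, 10)],
        ),
        ProteinRecord("P3", "MMMMMMMMMM", organism="org_b"),
    ]


UNIPROT_XML = """<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
<entry dataset="Swiss-Prot">
  <accession>P00001</accession>
  <organism>
    <name type="scientific">Testus exemplaris</name>
    <lineage><taxon>Bacteria</taxon><taxon>Testales</taxon></lineage>
  </organism>
  <feature type="transmembrane region" description="Helical" evidence="1">
    <location><begin position="10"/><end position="30"/></location>
  </feature>
  <feature type="transmembrane region" description="Helical" evidence="2">
    <location><begin position="40"/><end position="55"/></location>
  </feature>
  <feature type="chain" description="whole">
    <location><begin position="1"/><end position="60"/></location>
  </feature>
  <evidence key="1" type="ECO:0000269"/>
  <evidence key="2" type="ECO:0000255"/>
  <sequence length="60" checksum="X" modified="2000-01-01" version="1">
  MKTAYIAKQRGAAAGLLLLAVILGLVGGSSSMKTAYIAKQRGAAAGLLLLAVILGLVGGS
  </sequence>
</entry>
</uniprot>
"""

NO_TM_XML = """<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
<entry><accession>P00002</accession>
  <sequence>MKTAYIAKQR</sequence>
</entry>
</uniprot>
"""


@pytest.fixture
def uniprot_xml(tmp_path):
    p = tmp_path / "entry.xml"
    p.write_text(UNIPROT_XML)
    return p


@pytest.fixture
def uniprot_xml_no_tm(tmp_path):
    p = tmp_path / "no_tm.xml"
    p.write_text(NO_TM_XML)
    return p
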