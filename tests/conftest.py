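import pytest

from tcmdiag import ClinicalCase

# the two classic worked-example rows: a disease/syndrome "Heat" observed
# twice with overlapping symptom lists
HEAT_ROWS_CSV = """\
disease,syndrome,symptoms
Heat,Heat,"heat,dizzy,redface"
Heat,Heat,"heat,dizzy,sore throat"
"""

# RDF/XML fragment declaring three equivalent names for one syndrome
EQUIVALENCE_XML = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
<owl:Class rdf:about="Deficient cold syndrome">
  <owl:equivalentClass rdf:resource="Cold syndrome"/>
  <owl:equivalentClass rdf:resource="Yang deficient syndrome"/>
</owl:Class>
</rdf:RDF>
"""

# RDF/XML fragment declaring a compound syndrome subsuming two parts and
# inheriting from a category class
SUBSUME_XML = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
<owl:Class rdf:about="Qi stagnation and blood stasis">
  <owl:equivalentClass>
    <owl:Restriction>
      <owl:onProperty rdf:resource="subsume"/>
      <owl:someValuesFrom rdf:resource="Qi stagnation syndrome"/>
    </owl:Restriction>
  </owl:equivalentClass>
  <owl:equivalentClass>
    <owl:Restriction>
      <owl:onProperty rdf:resource="subsume"/>
      <owl:someValuesFrom rdf:resource="Blood stasis syndrome"/>
    </owl:Restriction>
  </owl:equivalentClass>
  <rdfs:subClassOf rdf:resource="Excess syndrome"/>
</owl:Class>
</rdf:RDF>
"""


@pytest.fixture
def heat_cases_file(tmp_path):
    path = tmp_path / "heat.csv"
    path.write_text(HEAT_ROWS_CSV, encoding="utf-8")
    return path


@pytest.fixture
def heat_cases():
    return [
        ClinicalCase("Heat", "Heat", ("heat", "dizzy", "redface")),
        ClinicalCase("Heat", "Heat", ("heat", "dizzy", "sore throat")),
    ]
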