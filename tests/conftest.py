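import pytest
from hypothesis import HealthCheck, settings

from meshindex import parse_thesaurus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# The Lymphoma descriptor and its full ancestor chain, as printed in the
# MeSH reference material: Lymphoma holds tree numbers C04.557.386,
# C15.604.515.569 and C20.683.515.761, i.e. it lives in three branches at
# once.  Lymphoproliferative Disorders is a single descriptor occupying two
# positions (C15.604.515 and C20.683.515).
LYMPHOMA_TSV = """\
D006402\tHemic and Lymphatic Diseases\tC15
D007154\tImmune System Diseases\tC20
D007160\tImmunoproliferative Disorders\tC20.683
D008206\tLymphatic Diseases\tC15.604
D008223\tLymphoma\tC04.557.386;C15.604.515.569;C20.683.515.761
D008232\tLymphoproliferative Disorders\tC15.604.515;C20.683.515
D009369\tNeoplasms\tC04
D009370\tNeoplasms by Histologic Type\tC04.557
"""

LYMPHOMA = "D008223"
LYMPHOPROLIFERATIVE = "D008232"

# Synthetic mini-thesaurus reproducing the published worked example of the
# broader-heading rule: "Lymphoma, B-Cell", "Ataxia Telangiectasia" and
# "Lymphoma" all sit under "Immune System Diseases" (their LCA), while the
# other proposed headings occupy branches that never put three labels under
# one shared descriptor.  Tree numbers outside the C20 chain are invented.
TABLE3_TSV = """\
D000818\tAnimals\tB05.100
D001260\tAtaxia Telangiectasia\tC20.111
D001402\tB-Lymphocytes\tA11.118
D004268\tDNA-Binding Proteins\tD13.100
D006801\tHumans\tB01.050
D007154\tImmune System Diseases\tC20
D007160\tImmunoproliferative Disorders\tC20.683
D008223\tLymphoma\tC20.683.515.761
D008232\tLymphoproliferative Disorders\tC20.683.515
D016393\tLymphoma, B-Cell\tC20.683.515.761.155
D016889\tGenomic Instability\tG05.365
D017346\tProtein-Serine-Threonine Kinases\tD08.600
D017404\tIn Situ Hybridization, Fluorescence\tE05.478
D018345\tMice, Knockout\tB02.075
D018797\tCell Cycle Proteins\tD12.776
D019919\tCyclin D1\tD12.300
D064007\tAtaxia Telangiectasia Mutated Proteins\tD08.811
"""

TABLE3_LABELS = [
    "D064007",  # Ataxia Telangiectasia Mutated Proteins
    "D001402",  # B-Lymphocytes
    "D018797",  # Cell Cycle Proteins
    "D004268",  # DNA-Binding Proteins
    "D006801",  # Humans
    "D017346",  # Protein-Serine-Threonine Kinases
    "D000818",  # Animals
    "D016889",  # Genomic Instability
    "D018345",  # Mice, Knockout
    "D019919",  # Cyclin D1
    "D017404",  # In Situ Hybridization, Fluorescence
    "D016393",  # Lymphoma, B-Cell
    "D001260",  # Ataxia Telangiectasia
    "D008223",  # Lymphoma
]


@pytest.fixture(scope="session")
def lymphoma_thesaurus():
    return parse_thesaurus(LYMPHOMA_TSV)


@pytest.fixture(scope="session")
def table3_thesaurus():
    return parse_thesaurus(TABLE3_TSV)
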