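"""Reading and writing models, and mapping metabolomics features.

Round-trips the toy model through SBML Level 3 (+fbc) and the tabular
dialect, audits it, and matches an annotated feature table onto the
network by identifier priority (InChI > ChEBI > PubChem > name).
"""

import tempfile
from pathlib import Path

import pandas as pd

from fluxkit import (
    make_toy_model,
    match_metabolites,
    read_sbml,
    read_tabular_model,
    validate_model,
    write_sbml,
    write_tabular_model,
)
from fluxkit.cli import structural_diff

model = make_toy_model()
with tempfile.TemporaryDirectory() as tmp:
    sbml = Path(tmp) / "model.xml"
    xlsx = Path(tmp) / "model.xlsx"
    write_sbml(model, sbml)
    write_tabular_model(model, xlsx)
    print(f"SBML round trip differences:    {structural_diff(model, read_sbml(sbml))}")
    print(f"tabular round trip differences: "
          f"{structural_diff(model, read_tabular_model(xlsx))}")

findings = validate_model(model)
print(f"validation: {sum(f.severity == 'error' for f in findings)} errors, "
      f"{sum(f.severity == 'info' for f in findings)} coverage statistics")

features = pd.DataFrame([
    {"name": "unknown peak", "chebi": "CHEBI:15361"},        # pyruvate by ChEBI
    {"name": "D-glucose", "inchi": "", "chebi": ""},         # by name
    {"name": "mystery compound", "chebi": "CHEBI:00000"},    # no hit
])
result = match_metabolites(model, features)
for match in result.matches:
    print(f"feature {match.feature_index}: matched {match.metabolite_ids or '-'} "
          f"via {match.matched_by}")
print(f"coverage: {result.coverage:.2f}")
# Identifier-based matching links untargeted metabolomics features to model
# species; a name only decides when no structural identifier is available.
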