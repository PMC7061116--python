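# Standard 2015 guideline combination table. Differs from paper_verbatim in
# two places: the likely-pathogenic ">=3 supporting" line is ">=3 moderate"
# here, and the pathogenic "PVS1 + 1 moderate + 1 supporting" line is present.
name: acmg2015
lines:
  - {name: "1 PVS1 + >=1 PS", tier: pathogenic, min: {PVS: 1, PS: 1}}
  - {name: "1 PVS1 + >=2 PM", tier: pathogenic, min: {PVS: 1, PM: 2}}
  - {name: "1 PVS1 + 1 PS + 1 PM", tier: pathogenic, min: {PVS: 1, PS: 1, PM: 1}}
  - {name: "1 PVS1 + 1 PM + 1 PP", tier: pathogenic, min: {PVS: 1, PM: 1, PP: 1}}
  - {name: "1 PVS1 + >=2 PP", tier: pathogenic, min: {PVS: 1, PP: 2}}
  - {name: ">=2 PS", tier: pathogenic, min: {PS: 2}}
  - {name: "1 PS + >=3 PM", tier: pathogenic, min: {PS: 1, PM: 3}}
  - {name: "1 PS + 2 PM + >=2 PP", tier: pathogenic, min: {PS: 1, PM: 2, PP: 2}}
  - {name: "1 PS + 1 PM + >=4 PP", tier: pathogenic, min: {PS: 1, PM: 1, PP: 4}}
  - {name: "1 PVS1 + 1 PM", tier: likely_pathogenic, min: {PVS: 1, PM: 1}}
  - {name: "1 PS + 1-2 PM", tier: likely_pathogenic, min: {PS: 1, PM: 1}}
  - {name: "1 PS + >=2 PP", tier: likely_pathogenic, min: {PS: 1, PP: 2}}
  - {name: ">=3 PM", tier: likely_pathogenic, min: {PM: 3}}
  - {name: "2 PM + >=2 PP", tier: likely_pathogenic, min: {PM: 2, PP: 2}}
  - {name: "1 PM + >=4 PP", tier: likely_pathogenic, min: {PM: 1, PP: 4}}
  - {name: "1 BA1", tier: benign, min: {BA: 1}}
  - {name: ">=2 BS", tier: benign, min: {BS: 2}}
  - {name: "1 BS + 1 BP", tier: likely_benign, min: {BS: 1, BP: 1}}
  - {name: ">=2 BP", tier: likely_benign, min: {BP: 2}}
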