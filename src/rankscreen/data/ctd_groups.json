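{
  "_comment": "Three-group amino-acid classifications for the seven physicochemical properties used by the composition/transition/distribution (CTD) protein sequence features. These are the standard group tables of the CTD descriptor literature. Group order within each property is fixed and determines feature order.",
  "properties": [
    {
      "name": "hydrophobicity",
      "groups": ["RKEDQN", "GASTPHY", "CLVIMFW"],
      "group_labels": ["polar", "neutral", "hydrophobic"]
    },
    {
      "name": "normalized_vdw_volume",
      "groups": ["GASTPDC", "NVEQIL", "MHKFRYW"],
      "group_labels": ["0-2.78", "2.95-4.0", "4.03-8.08"]
    },
    {
      "name": "polarity",
      "groups": ["LIFWCMVY", "PATGS", "HQRKNED"],
      "group_labels": ["4.9-6.2", "8.0-9.2", "10.4-13.0"]
    },
    {
      "name": "polarizability",
      "groups": ["GASDT", "CPNVEQIL", "KMHFRYW"],
      "group_labels": ["0-0.108", "0.128-0.186", "0.219-0.409"]
    },
    {
      "name": "charge",
      "groups": ["KR", "ANCQGHILMFPSTWYV", "DE"],
      "group_labels": ["positive", "neutral", "negative"]
    },
    {
      "name": "secondary_structure",
      "groups": ["EALMQKRH", "VIYCWFT", "GNPSD"],
      "group_labels": ["helix", "strand", "coil"]
    },
    {
      "name": "solvent_accessibility",
      "groups": ["ALFCGIVW", "RKQEND", "MSPTHY"],
      "group_labels": ["buried", "exposed", "intermediate"]
    }
  ]
}
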