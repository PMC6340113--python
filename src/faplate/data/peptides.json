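{
  "CaMBD1a": {
    "ryr2_span": [1942, 1966],
    "sequence": "RFRYNEVMQALNMSAALTARKTKEF",
    "modifications": [],
    "label": "5-TAMRA"
  },
  "CaMBD1b": {
    "ryr2_span": [2022, 2052],
    "sequence": "DLTIRGRLLSLVEKVTYLKKKQAEKPVESDS",
    "modifications": [],
    "label": "5-TAMRA"
  },
  "CaMBD1b+P": {
    "ryr2_span": [2022, 2052],
    "sequence": "DLTIRGRLLSLVEKVTYLKKKQAEKPVESDS",
    "modifications": [{"kind": "phospho", "residue": "S", "position": 2031}],
    "label": "5-TAMRA"
  },
  "CaMBD2": {
    "ryr2_span": [3581, 3607],
    "sequence": "RSKKAVWHKLLSKQRKRAVVACFRMAP",
    "modifications": [],
    "label": "5-TAMRA"
  },
  "CaMBD2(+)": {
    "ryr2_span": [3581, 3611],
    "sequence": "RSKKAVWHKLLSKQRKRAVVACFRMAPLYNL",
    "modifications": [],
    "label": "5-TAMRA"
  },
  "CaMBD2(+)-W/A": {
    "ryr2_span": [3581, 3611],
    "sequence": "RSKKAVAHKLLSKQRKRAVVACFRMAPLYNL",
    "modifications": [{"kind": "substitution", "wt": "W", "position": 3587, "mut": "A"}],
    "label": "5-TAMRA"
  },
  "CaMBD2(+)-F/A": {
    "ryr2_span": [3581, 3611],
    "sequence": "RSKKAVWHKLLSKQRKRAVVACARMAPLYNL",
    "modifications": [{"kind": "substitution", "wt": "F", "position": 3603, "mut": "A"}],
    "label": "5-TAMRA"
  },
  "CaMBD3": {
    "ryr2_span": [4246, 4276],
    "sequence": "FALRYNILTLMRMLSLKSLKKQMKKVKKMTV",
    "modifications": [],
    "label": "5-TAMRA"
  },
  "null_probe": {
    "ryr2_span": null,
    "sequence": "",
    "modifications": [],
    "label": "5-TAMRA"
  }
}
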