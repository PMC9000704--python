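[
  {
    "table": "flavonoid_descriptors",
    "row": 30,
    "field": "all",
    "note": "Rows 8 and 30 are identical duplicate entries for 2'-Methoxykurarinone (printed twice with different literature references); both retained verbatim."
  },
  {
    "table": "flavonoid_descriptors",
    "row": 46,
    "field": "mw",
    "note": "Silydianin MW printed as 460.265 here but as 482.12 in the binding-affinity table and 482.4 g/mol in the discussion; never reconciled in the source, all values retained as printed."
  },
  {
    "table": "binding_affinity",
    "row": 5,
    "field": "n_heavy",
    "note": "Salacinol heavy-atom count from its molecular formula (19, C9H18O8S2) does not reproduce the printed ligand efficiency (-7.13/19 = -0.375 vs printed -0.36); left absent rather than guessed."
  },
  {
    "table": "reference_splits",
    "sort_key": "nrot",
    "ratio": "70:30",
    "part": "test",
    "ids": [46],
    "note": "Printed test list repeats id 46, which belongs to the training list (nrot = 3)."
  },
  {
    "table": "reference_splits",
    "sort_key": "nrot",
    "ratio": "75:25",
    "part": "test",
    "ids": [46],
    "note": "Printed test list repeats id 46, which belongs to the training list (nrot = 3)."
  },
  {
    "table": "reference_splits",
    "sort_key": "nrot",
    "ratio": "25:75",
    "part": "test",
    "ids": [46],
    "note": "Printed test list contains id 46 twice; the second occurrence (after id 37) is spurious."
  },
  {
    "table": "reference_splits",
    "sort_key": "logp",
    "ratio": "50:50",
    "part": "test",
    "ids": [29, 39],
    "note": "Printed test list shows id 39 twice and omits id 29; the LogP ordering places 29 between 34 and 8 where the second 39 is printed."
  },
  {
    "table": "reference_splits",
    "sort_key": "logp",
    "ratio": "70:30",
    "part": "test",
    "ids": [29, 39],
    "note": "Printed test list shows id 39 (already in the training list) in place of id 29."
  },
  {
    "table": "reference_splits",
    "sort_key": "logp",
    "ratio": "75:25",
    "part": "test",
    "ids": [29, 39],
    "note": "Printed test list shows id 39 (already in the training list) in place of id 29."
  },
  {
    "table": "reference_splits",
    "sort_key": "logp",
    "ratio": "25:75",
    "part": "test",
    "ids": [29, 39],
    "note": "Printed test list shows id 39 twice and omits id 29."
  }
]
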