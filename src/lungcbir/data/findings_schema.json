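{
  "schema_version": "1.0",
  "description": "Voxel label dialect for parenchymal finding volumes: 26 finding categories plus reserved auxiliary codes. Each finding carries its coarse group (the 11-group regrouping used for wide regions) and a lesion flag (everything except normal lung and borderline-normal counts as lesion).",
  "auxiliary_codes": {
    "0": "background / outside lung",
    "27": "airway",
    "28": "vessel"
  },
  "coarse_groups": {
    "1": "Consolidation + Pleural effusion + Pleural thickening",
    "2": "Ground-glass opacity + Centrilobular Ground-glass opacity",
    "3": "Tree-in-bud appearance + Small nodules (not centrilobular) + Centrilobular nodules",
    "4": "Interlobular septal thickening",
    "5": "Hyperlucency + Centrilobular emphysema + Panlobular emphysema",
    "6": "Cyst",
    "7": "Cavity surrounded by infiltration + Cavity surrounded by mass",
    "8": "Bronchial wall thickening + Bronchiectasis + Air bronchogram + Traction bronchiectasis",
    "9": "Normal lungs + Borderline between normal and hyperlucency + Faint ground-glass opacity + Borderline dilatation of bronchioles",
    "10": "Honeycombing",
    "11": "Reticulation + Fine reticulation"
  },
  "findings": [
    {"code": 1, "name": "Consolidation", "group": 1, "lesion": true},
    {"code": 2, "name": "Pleural effusion", "group": 1, "lesion": true},
    {"code": 3, "name": "Pleural thickening", "group": 1, "lesion": true},
    {"code": 4, "name": "Ground-glass opacity", "group": 2, "lesion": true},
    {"code": 5, "name": "Centrilobular Ground-glass opacity", "group": 2, "lesion": true},
    {"code": 6, "name": "Tree-in-bud appearance", "group": 3, "lesion": true},
    {"code": 7, "name": "Small nodules (not centrilobular)", "group": 3, "lesion": true},
    {"code": 8, "name": "Centrilobular nodules", "group": 3, "lesion": true},
    {"code": 9, "name": "Interlobular septal thickening", "group": 4, "lesion": true},
    {"code": 10, "name": "Hyperlucency", "group": 5, "lesion": true},
    {"code": 11, "name": "Centrilobular emphysema", "group": 5, "lesion": true},
    {"code": 12, "name": "Panlobular emphysema", "group": 5, "lesion": true},
    {"code": 13, "name": "Cyst", "group": 6, "lesion": true},
    {"code": 14, "name": "Cavity surrounded by infiltration", "group": 7, "lesion": true},
    {"code": 15, "name": "Cavity surrounded by mass", "group": 7, "lesion": true},
    {"code": 16, "name": "Bronchial wall thickening", "group": 8, "lesion": true},
    {"code": 17, "name": "Bronchiectasis", "group": 8, "lesion": true},
    {"code": 18, "name": "Air bronchogram", "group": 8, "lesion": true},
    {"code": 19, "name": "Traction bronchiectasis", "group": 8, "lesion": true},
    {"code": 20, "name": "Normal lung", "group": 9, "lesion": false},
    {"code": 21, "name": "Borderline between normal and hyperlucency", "group": 9, "lesion": false},
    {"code": 22, "name": "Faint ground-glass opacity", "group": 9, "lesion": true},
    {"code": 23, "name": "Borderline dilatation of bronchioles", "group": 9, "lesion": true},
    {"code": 24, "name": "Honeycombing", "group": 10, "lesion": true},
    {"code": 25, "name": "Reticulation", "group": 11, "lesion": true},
    {"code": 26, "name": "Fine reticulation", "group": 11, "lesion": true}
  ]
}
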