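{
  "shh_set": ["SHH", "NKX6-1", "NKX6-2", "NKX2-2", "NKX2-1", "FOXA2", "FOXG1", "OLIG2"],
  "shh_module": ["SHH", "FOXA2", "NKX2-2", "OLIG2", "NKX6-1", "NKX6-2", "PTCH1", "HHIP"],
  "floor_plate": ["FOXA2", "NKX6-1", "SHH", "FERDL3L", "ARX", "LMX1B"],
  "p3": ["NKX6-1", "NKX2-2", "NKX2-9"],
  "pMN": ["SP8", "NKX6-1", "OLIG2"],
  "p0-2": ["IRX3", "IRX5", "PAX6", "DBX2", "DBX1", "SP8", "NKX6-2", "PRDM12", "NKX6-1", "FOXN4"],
  "dp1-6": ["MSX2", "PAX3", "OLIG3", "IRX3", "IRX5", "PAX6", "PAX7", "GSX2", "ASCL1", "GSX1", "GBX2", "DBX2", "DBX1", "SP8"],
  "roof_plate": ["LMX1A", "MSX1", "MSX2", "PAX3", "WNT1"]
}
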