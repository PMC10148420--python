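{
 "terms": [
  {"a": "VIM-AS1", "b": "AC005083.1", "beta": 0.5447},
  {"a": "LINC01057", "b": "RP11-43F13.3", "beta": 0.7797},
  {"a": "TNRC6C-AS1", "b": "RP11-395G23.3", "beta": 1.0279},
  {"a": "NRSN2-AS1", "b": "LINC01554", "beta": -0.7839},
  {"a": "PCED1B-AS1", "b": "AC079466.1", "beta": 0.7766},
  {"a": "LINC00342", "b": "CASC9", "beta": 1.0191},
  {"a": "RP1-239B22.5", "b": "RP11-344B5.2", "beta": -0.7017},
  {"a": "PSMB8-AS1", "b": "ANKRD10-IT1", "beta": 0.7464},
  {"a": "KB-68A7.1", "b": "ZFPM2-AS1", "beta": 0.6299},
  {"a": "FOXD2-AS1", "b": "AC092580.4", "beta": -0.5646},
  {"a": "LINC00942", "b": "RP11-109M17.2", "beta": -1.3199}
 ],
 "threshold": 0.025,
 "horizon_years": 5.0,
 "provenance": "published"
}
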