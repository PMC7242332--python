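{
 "sectors": [
  ["A", "B", "C", "D", "E", "F", "G", "H", "I"],
  ["J", "K", "L", "M", "N", "O", "P", "Q", "R"],
  ["S", "T", "U", "V", "W", "X", "Y", "Z"],
  ["SPACE", "BACKSPACE", "DELETE_WORD"]
 ],
 "special_sector": 3
}
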