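# Alias -> canonical exporter-name map used before joining trade ledgers
# against the nation profile table. Matching is exact after lookup.
aliases:
  "China": "The Mainland of China"
  "Mainland China": "The Mainland of China"
  "People's Republic of China": "The Mainland of China"
  "Taiwan": "Taiwan Province of China"
  "Chinese Taipei": "Taiwan Province of China"
  "Hong Kong SAR": "Hong Kong"
  "Hong Kong S.A.R.": "Hong Kong"
  "Macao": "Macau"
  "UAE": "United Arab Emirates"
  "USA": "United States"
  "United States of America": "United States"
  "Republic of Korea": "South Korea"
  "Korea, Republic of": "South Korea"
  "Viet Nam": "Vietnam"
  "Cote d'Ivoire": "Cote D'Ivoire"
  "Ivory Coast": "Cote D'Ivoire"
  "Solomon Islands": "Solomon Is"
  "Trinidad and Tobago": "Trinidad & Tobago"
  "Congo, Democratic Republic of the": "Democratic Republic of the Congo"
  "DR Congo": "Democratic Republic of the Congo"
  "Republic of the Congo": "Congo"
  "Iran, Islamic Republic of": "Iran"
  "Tanzania, United Republic of": "Tanzania"
  "Venezuela, Bolivarian Republic of": "Venezuela"
  "Bolivia, Plurinational State of": "Bolivia"
  "Turkiye": "Turkey"
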