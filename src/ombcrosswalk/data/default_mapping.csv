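term,code,provenance
cherokee,AIAN,federally recognized tribe (illustrative list)
navajo,AIAN,federally recognized tribe (illustrative list)
sioux,AIAN,federally recognized tribe (illustrative list)
chippewa,AIAN,federally recognized tribe (illustrative list)
choctaw,AIAN,federally recognized tribe (illustrative list)
apache,AIAN,federally recognized tribe (illustrative list)
native american,AIAN,category label
american indian,AIAN,category label
alaska native,AIAN,category label
aian,AIAN,category abbreviation
indian,ASIAN,Federal Register definition (Indian subcontinent)
asian indian,ASIAN,category label
japanese,ASIAN,Federal Register definition
vietnamese,ASIAN,Federal Register definition
chinese,ASIAN,Federal Register definition
korean,ASIAN,Federal Register definition
filipino,ASIAN,Federal Register definition
cambodian,ASIAN,Federal Register definition
thai,ASIAN,Federal Register definition
pakistani,ASIAN,Federal Register definition
malaysian,ASIAN,Federal Register definition
asian,ASIAN,category label
asian american,ASIAN,category label
haitian,BLACK,Federal Register definition
malian,BLACK,curator decision (Black racial groups of Africa)
west african,BLACK,curator decision (Black racial groups of Africa)
cape verdean,BLACK,curator decision
jamaican,BLACK,curator decision
nigerian,BLACK,curator decision
ethiopian,BLACK,curator decision
somali,BLACK,curator decision
african,BLACK,curator decision
black,BLACK,category label
african american,BLACK,category label
negro,BLACK,Federal Register definition (term usable in addition)
central american,HISPANIC,Federal Register definition
south american,HISPANIC,Federal Register definition
el salvadorean,HISPANIC,curator decision
salvadoran,HISPANIC,curator decision
puerto rican,HISPANIC,Federal Register definition
cuban,HISPANIC,Federal Register definition
mexican,HISPANIC,Federal Register definition
dominican,HISPANIC,curator decision
colombian,HISPANIC,curator decision
guatemalan,HISPANIC,curator decision
hispanic,HISPANIC,category label
latino,HISPANIC,category label
latina,HISPANIC,category label
spanish,HISPANIC,Federal Register definition (Spanish origin)
polynesian,NHPI,Federal Register definition
hawaiian,NHPI,Federal Register definition
native hawaiian,NHPI,category label
tahitian,NHPI,curator decision
samoan,NHPI,Federal Register definition
guamanian,NHPI,Federal Register definition
tongan,NHPI,curator decision
fijian,NHPI,curator decision
pacific islander,NHPI,category label
austrian,WHITE,curator decision (original peoples of Europe)
dutch,WHITE,curator decision (original peoples of Europe)
lebanese,WHITE,Federal Register definition (Middle East maps to White pre-2024)
german,WHITE,curator decision (original peoples of Europe)
french,WHITE,curator decision (original peoples of Europe)
irish,WHITE,curator decision (original peoples of Europe)
italian,WHITE,curator decision (original peoples of Europe)
english,WHITE,curator decision (original peoples of Europe)
portuguese,WHITE,curator decision (original peoples of Europe)
greek,WHITE,curator decision (original peoples of Europe)
polish,WHITE,curator decision (original peoples of Europe)
russian,WHITE,curator decision (original peoples of Europe)
middle eastern,WHITE,pre-2024 standard maps MENA to White
arab,WHITE,pre-2024 standard maps MENA to White
egyptian,WHITE,pre-2024 standard maps MENA to White
white,WHITE,category label
caucasian,WHITE,category label
american,UNMAPPED,does not map to a federal category
brazilian,UNMAPPED,excluded from the federal Hispanic or Latino definition
jewish,UNMAPPED,religion; does not map to a federal category
muslim,UNMAPPED,religion; does not map to a federal category
united states,UNMAPPED,does not map to a federal category
massachusetts,UNMAPPED,does not map to a federal category
mixed,UNMAPPED,no single federal category
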