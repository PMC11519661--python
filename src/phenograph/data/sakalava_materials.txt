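typeStatus: Holotype
catalogNumber: http://id.luomus.fi/GZ.15827
recordedBy: I. Hanski group
individualCount: 1
sex: male
lifeStage: adult
occurrenceID: 16BD880A-0D65-5B0E-909A-A3DDD3A4D1A8
taxonID: urn:lsid:biosci.ohio-state.edu:osuc_names:275502
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Ambadira-Morondava
verbatimLocality: Ambadira-Mormdava
decimalLatitude: -19.8299
decimalLongitude: 44.6403
georeferenceRemarks: coordinates inferred from locality name
identifiedBy: Giulio Montanaro
dateIdentified: 2023
samplingProtocol: cattle dung
eventDate: 12-2006
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.15828
recordedBy: I. Hanski group
individualCount: 1
sex: female
lifeStage: adult
occurrenceID: 54A6436B-20BF-5615-9B08-048D138D820E
taxonID: urn:lsid:biosci.ohio-state.edu:osuc_names:275502
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Ambadira-Morondava
verbatimLocality: Ambadira-Mormdava
decimalLatitude: -19.8299
decimalLongitude: 44.6403
georeferenceRemarks: coordinates inferred from locality name
identifiedBy: Giulio Montanaro
dateIdentified: 2023
samplingProtocol: cattle dung
eventDate: 12-2006
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.15818
recordedBy: Ilkka Hanski
individualCount: 1
sex: male
lifeStage: adult
occurrenceID: 341C47FD-A05B-53A0-99AB-30725CE58997
taxonID: urn:lsid:biosci.ohio-state.edu:osuc_names:275502
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Marofandilia
decimalLatitude: -20.1327
decimalLongitude: 44.5503
georeferenceRemarks: coordinates inferred from locality name
identifiedBy: Giulio Montanaro
dateIdentified: 2023
samplingProtocol: fish baited trap
eventDate: 04-2004
habitat: dry deciduous forest corridor
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.15817
recordedBy: Ilkka Hanski
individualCount: 1
sex: male
lifeStage: adult
occurrenceID: F6002F94-267E-5CBB-802A-F519E4BEC873
taxonID: urn:lsid:biosci.ohio-state.edu:osuc_names:275502
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Marofandilia
decimalLatitude: -20.1327
decimalLongitude: 44.5503
georeferenceRemarks: coordinates inferred from locality name
identifiedBy: Giulio Montanaro
dateIdentified: 2023
samplingProtocol: fish baited trap
eventDate: 04-2004
habitat: dry deciduous forest corridor
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.15816
recordedBy: Ilkka Hanski
individualCount: 1
sex: male
lifeStage: adult
occurrenceID: 7722D749-3E83-50B3-BB60-38B86F7F2477
taxonID: urn:lsid:biosci.ohio-state.edu:osuc_names:275502
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Marofandilia
decimalLatitude: -20.1327
decimalLongitude: 44.5503
georeferenceRemarks: coordinates inferred from locality name
identifiedBy: Giulio Montanaro
dateIdentified: 2023
samplingProtocol: fish baited trap
eventDate: 04-2004
habitat: dry deciduous forest corridor
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.57485
recordedBy: Sergei Tarasov
individualCount: 1
sex: female
lifeStage: adult
occurrenceID: 2E216A5E-330D-5C21-9711-BB32E3B096D8
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Morondava, Kirindy station
verbatimElevation: 71 m
verbatimCoordinates: -20.066805, 44.657255
decimalLatitude: -20.066805
decimalLongitude: 44.657255
georeferenceProtocol: GPS
identifiedBy: Giulio Montanaro
dateIdentified: 2023
eventID: MG22-29a
samplingProtocol: human dung traps
eventDate: 03/07-03-2022
habitat: dry forest
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.57486
recordedBy: Sergei Tarasov
individualCount: 1
sex: male
lifeStage: adult
occurrenceID: 055DDC5A-D731-5DB6-9A9C-B4359C2E84C5
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Morondava, Kirindy station
verbatimElevation: 71 m
verbatimCoordinates: -20.066805, 44.657255
decimalLatitude: -20.066805
decimalLongitude: 44.657255
georeferenceProtocol: GPS
identifiedBy: Giulio Montanaro
dateIdentified: 2023
eventID: MG22-29a
samplingProtocol: human dung traps
eventDate: 03/07-03-2022
habitat: dry forest
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.57487
recordedBy: Sergei Tarasov
individualCount: 1
sex: female
lifeStage: adult
occurrenceID: 64E02FAA-3180-51C1-9ACC-C9E42D0C3020
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Morondava, Kirindy station
verbatimElevation: 71 m
verbatimCoordinates: -20.066805, 44.657255
decimalLatitude: -20.066805
decimalLongitude: 44.657255
georeferenceProtocol: GPS
identifiedBy: Giulio Montanaro
dateIdentified: 2023
eventID: MG22-29a
samplingProtocol: human dung traps
eventDate: 03/07-03-2022
habitat: dry forest
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen

typeStatus: Paratype
catalogNumber: http://id.luomus.fi/GZ.57488
recordedBy: Sergei Tarasov
individualCount: 1
sex: female
lifeStage: adult
occurrenceID: 42053262-8E9F-5379-AD6C-6A6A57AA3507
scientificName: Scarabaeussakalava
genus: Scarabaeus
specificEpithet: sakalava
scientificNameAuthorship: Montanaro & Tarasov
country: Madagascar
stateProvince: Toliara
locality: Morondava, Kirindy station
verbatimElevation: 71 m
verbatimCoordinates: -20.066805, 44.657255
decimalLatitude: -20.066805
decimalLongitude: 44.657255
georeferenceProtocol: GPS
identifiedBy: Giulio Montanaro
dateIdentified: 2023
eventID: MG22-29a
samplingProtocol: human dung traps
eventDate: 03/07-03-2022
habitat: dry forest
institutionID: http://grbio.org/cool/2vmj-fp0v
institutionCode: MZH
basisOfRecord: PreservedSpecimen
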