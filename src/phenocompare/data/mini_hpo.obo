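format-version: 1.2
data-version: phenocompare/mini/1.0
ontology: mini-hp

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000478
name: Abnormality of the eye
is_a: HP:0000001 ! All

[Term]
id: HP:0000539
name: Abnormality of refraction
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000545
name: Myopia
alt_id: HP:9999991
is_a: HP:0000539 ! Abnormality of refraction

[Term]
id: HP:0025573
name: Mild myopia
is_a: HP:0000545 ! Myopia

[Term]
id: HP:0000540
name: Hypermetropia
is_a: HP:0000539 ! Abnormality of refraction

[Term]
id: HP:0000496
name: Abnormal eye movement
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000639
name: Nystagmus
is_a: HP:0000496 ! Abnormal eye movement

[Term]
id: HP:0000486
name: Strabismus
is_a: HP:0000496 ! Abnormal eye movement

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000001 ! All

[Term]
id: HP:0012638
name: Abnormal nervous system physiology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001250
name: Seizure
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002121
name: Absence seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0007359
name: Focal-onset seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0011097
name: Epileptic spasm
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0001252
name: Hypotonia
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001263
name: Global developmental delay
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0100022
name: Abnormality of movement
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001251
name: Ataxia
is_a: HP:0100022 ! Abnormality of movement
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001332
name: Dystonia
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0001337
name: Tremor
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0012443
name: Abnormality of brain morphology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0002126
name: Polymicrogyria
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0001272
name: Cerebellar atrophy
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0000252
name: Microcephaly
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0025031
name: Abnormality of the digestive system
is_a: HP:0000001 ! All

[Term]
id: HP:0002019
name: Constipation
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0002020
name: Gastroesophageal reflux
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0011968
name: Feeding difficulties
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0002015
name: Dysphagia
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0002086
name: Abnormality of the respiratory system
is_a: HP:0000001 ! All

[Term]
id: HP:0002099
name: Asthma
is_a: HP:0002086 ! Abnormality of the respiratory system

[Term]
id: HP:0002205
name: Recurrent respiratory infections
is_a: HP:0002086 ! Abnormality of the respiratory system

[Term]
id: HP:0025267
name: Snoring
is_a: HP:0002086 ! Abnormality of the respiratory system

[Term]
id: HP:0001742
name: Nasal congestion
is_a: HP:0002086 ! Abnormality of the respiratory system

[Term]
id: HP:0000164
name: Abnormality of the dentition
is_a: HP:0000001 ! All

[Term]
id: HP:0000670
name: Carious teeth
is_a: HP:0000164 ! Abnormality of the dentition

[Term]
id: HP:0000684
name: Delayed eruption of teeth
is_a: HP:0000164 ! Abnormality of the dentition

[Term]
id: HP:0000668
name: Dental crowding
is_a: HP:0000164 ! Abnormality of the dentition

[Term]
id: HP:0000704
name: Periodontitis
is_a: HP:0000164 ! Abnormality of the dentition

[Term]
id: HP:0001626
name: Abnormality of the cardiovascular system
is_a: HP:0000001 ! All

[Term]
id: HP:0001627
name: Abnormal heart morphology
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0001629
name: Ventricular septal defect
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0001631
name: Atrial septal defect
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0011675
name: Arrhythmia
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0002715
name: Abnormality of the immune system
is_a: HP:0000001 ! All

[Term]
id: HP:0002719
name: Recurrent infections
is_a: HP:0002715 ! Abnormality of the immune system

[Term]
id: HP:0004313
name: Decreased circulating antibody level
is_a: HP:0002715 ! Abnormality of the immune system

[Term]
id: HP:0000077
name: Abnormality of the kidney
is_a: HP:0000001 ! All

[Term]
id: HP:0000107
name: Renal cyst
is_a: HP:0000077 ! Abnormality of the kidney

[Term]
id: HP:0000085
name: Horseshoe kidney
is_a: HP:0000077 ! Abnormality of the kidney

[Term]
id: HP:0000818
name: Abnormality of the endocrine system
is_a: HP:0000001 ! All

[Term]
id: HP:0000821
name: Hypothyroidism
is_a: HP:0000818 ! Abnormality of the endocrine system

[Term]
id: HP:0000824
name: Growth hormone deficiency
is_a: HP:0000818 ! Abnormality of the endocrine system

[Term]
id: HP:0000598
name: Abnormality of the ear
is_a: HP:0000001 ! All

[Term]
id: HP:0000365
name: Hearing impairment
is_a: HP:0000598 ! Abnormality of the ear

[Term]
id: HP:0000388
name: Otitis media
is_a: HP:0000598 ! Abnormality of the ear

[Term]
id: HP:0008012
name: obsolete Severe myopia variant
is_obsolete: true
replaced_by: HP:0000545
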