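subject_id,sex,neutered,breed,age_months,condition,cmps,pain_suspected
1,m,Yes,European short haired cat,18,Foreign body,2,No
2,f,Yes,European short haired cat,92,Anemia,0,No
3,m,Yes,Maine Coone,22,Azotemia,1,No
4,m,Yes,European short haired cat,58,Anemia,1,No
5,f,Yes,European short haired cat,96,Anemia,2,No
6,m,Yes,British short haired cat,164,Intoxication,2,No
7,m,Yes,British short haired cat,68,Anemia,2,No
8,m,Yes,British short haired cat,20,Pneumothorax,0,No
9,m,No,British long haired cat,7,Paraneoplastic syndrome,2,No
10,m,Yes,Maine Coone,84,Otitis externa,1,No
11,f,Yes,European short haired cat,15,Seizures,1,No
12,m,No,British short haired cat,8,Paraparesis,0,No
13,m,Yes,European short haired cat,152,Hyphema,0,No
14,m,Yes,Sibirian forest cat,10,Vomiting,0,No
15,m,Yes,European short haired cat,40,Diaphragmatic rupture,1,No
16,m,Yes,European short haired cat,19,Ataxia,2,No
17,f,Yes,European short haired cat,163,Vomiting,2,No
18,m,Yes,European short haired cat,156,Corneal ulcer,0,No
19,f,Yes,Maine Coone,69,Anemia,2,No
20,m,No,Maine Coone,58,Lack of appetite,3,No
21,f,No,European short haired cat,unknown,Fracture of the humerus,1,No
22,m,Yes,European short haired cat,139,Avulsion of the tail,0,No
23,m,Yes,Ragdoll,55,Pulmonary edema,0,No
24,m,Yes,Maine Coone,29,Intestinal invagination,1,No
25,m,Yes,European short haired cat,79,Vomiting,0,No
26,m,Yes,Bengal cat,9,Vomiting,1,No
27,m,Yes,Ragdoll,115,Anemia,2,No
28,m,No,British short haired cat,72,Pulmonary edema,2,No
29,m,Yes,European short haired cat,56,Vomiting,0,No
30,f,Yes,Russian blue cat,165,Planned surgery on the eye,0,No
31,f,Yes,Exotic short haired cat,67,Anemia,0,No
32,f,Yes,Norwegian forest cat,140,Intestinal tumor,2,No
33,m,Yes,European short haired cat,168,Seizures,0,No
34,m,Yes,Maine Coone,46,Pleural effusion,1,No
35,f,Yes,European short haired cat,192,Pleural effusion,0,No
36,f,Yes,European short haired cat,103,Vomiting,0,No
37,m,Yes,British short haired cat,45,Enteral foreign body,3,No
38,f,No,British short haired cat,8,Lymphoma,1,No
39,m,Yes,European short haired cat,19,Lymphoma,0,No
40,m,Yes,European short haired cat,19,Cystitis,2,No
41,f,Yes,European short haired cat,134,Dyspnea,1,No
42,m,Yes,European short haired cat,113,Anemia,2,No
43,f,Yes,Birman cat,105,Pyometra,5,Yes
44,f,No,Siamese cat,24,Fracture of the femur,5,Yes
45,m,Yes,British short haired cat,15,Dislocation of the tarsal joint,6,Yes
46,f,Yes,Russian blue cat,101,Monoparesis,8,Yes
47,f,Yes,European short haired cat,130,Polytrauma,10,Yes
48,f,Yes,British short haired cat,19,Coprostasis,9,Yes
49,f,Yes,European short haired cat,156,Urolithiasis,5,Yes
50,m,Yes,European short haired cat,36,Cholecystopathy,7,Yes
51,m,Yes,British short haired cat,72,FLUTD,5,Yes
52,m,Yes,European short haired cat,19,Trauma after car accident,7,Yes
53,m,Yes,British short haired cat,27,Avulsion of the tail,5,Yes
54,f,Yes,European short haired cat,51,Pelvic fracture,5,Yes
55,m,Yes,European short haired cat,120,Lower jaw symphysiolysis,8,Yes
56,m,Yes,Russian blue cat,61,Pelvic fracture,8,Yes
57,m,Yes,European short haired cat,19,FLUTD,8,Yes
58,m,Yes,European short haired cat,144,Pleuroperitoneal hernia,6,Yes
59,m,Yes,British short haired cat,86,Fracture of the humerus,5,Yes
60,f,No,European short haired cat,unknown,Avulsion of the tail,7,Yes
61,m,Yes,European short haired cat,115,Intestinal invagination,5,Yes
62,m,Yes,Maine Coone,29,Polytrauma,5,Yes
63,m,Yes,European short haired cat,60,Corneal ulcer,7,Yes
64,m,Yes,European short haired cat,56,Pelvic fracture,6,Yes
65,m,Yes,British short haired cat,32,Fracture of the femur,6,Yes
66,f,Yes,Norwegian forest cat,18,Fracture of the femur,7,Yes
67,f,Yes,Norwegian forest cat,18,FLUTD,5,Yes
68,m,Yes,European short haired cat,88,FLUTD,5,Yes
69,m,Yes,European short haired cat,31,Fracture of radius and ulna,6,Yes
70,m,Yes,Bengal cat,67,Pelvic fracture,7,Yes
71,m,Yes,European short haired cat,18,Lameness,5,Yes
72,f,Yes,European short haired cat,74,Polytrauma,5,Yes
73,m,Yes,European short haired cat,132,FLUTD,6,Yes
74,m,Yes,European short haired cat,168,Meningoencephalytis,7,Yes
75,m,No,British long haired cat,7,Coprostasis,5,Yes
76,m,Yes,Sibirian forest cat,26,Pancreatitis,5,Yes
77,m,Yes,European short haired cat,127,Pelvic fracture,6,Yes
78,f,No,European short haired cat,14,Pelvic fracture,10,Yes
79,f,No,European short haired cat,10,Fracture of the femur,5,Yes
80,f,Yes,European short haired cat,60,Fracture of the femur,5,Yes
81,f,Yes,European short haired cat,124,Penis necrosis,7,Yes
82,m,Yes,European short haired cat,50,Peritonitis,11,Yes
83,f,Yes,European short haired cat,141,Fracture of the femur,7,Yes
84,m,No,European short haired cat,16,Polytrauma,5,Yes
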