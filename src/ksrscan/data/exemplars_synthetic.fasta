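>CC_SAM_EXEMPLAR synthetic CC-SAM domain exemplar
QTFLNAQWVLWNTIIALMQNNNLVLYAWQWIINWQLKFMVFVYIKWVKWQIMNAIFQLTV
VYANLWTLQKIFATWFQTTV
>RBD_EXEMPLAR synthetic RAS-binding domain exemplar
TQLITYLLYLKVNLQWMKKKFWTWMTNMQKVWTNMNYMFIFIYLMVYQKNLAWVLNYFNI
LLYKLAYNWYWFA
>KINASE_DOMAIN_EXEMPLAR synthetic canonical kinase domain exemplar
GSGSFGYKYKKKITVFVAVKMLNVTAPTPQLQAFNKEVGVALRKTRAYWNNFWFWTQKFQ
KMAIKQVAWYWQIMWIVNFANLAMWWAMMMWLAYTQMVYTMAVYFLNYKFHRDLKSNNIF
LHEDLTVKIGDFGLATVKSRYNWTYKQLYKWKFQTQNMAPE
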